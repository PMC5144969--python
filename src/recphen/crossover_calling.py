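"""Crossover detection in parents from sib-pair haplotype-sharing switches.

For each family, markers where the target parent is heterozygous and the
other parent homozygous are *informative*: at such a marker the allele each
child received from the target parent can be read off directly.  Comparing a
fixed reference child with each sibling yields a binary sharing sequence
(same/different transmitted allele); a switch in that sequence marks a
recombination in one of the two meioses.  Runs of fewer than ``min_run``
consecutive concordant markers are smoothed away before calling, which
removes the spurious tight double-recombinants genotyping error produces.
Events observed in more than one (reference, sibling) pair are consolidated
so each parental crossover is scored once.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import MISSING, GenotypeTable, MarkerMap, Pedigree

UNDETERMINED = -1

EVENT_COLUMNS = ["parent", "meiosis", "chrom", "start", "end",
                 "left_support", "right_support"]


@dataclass
class CrossoverEvent:
    """One inferred recombination, as a 0-based half-open uncertainty interval
    bounded by the flanking informative markers."""

    parent: str
    meiosis: str  # child id, or 'a|b' when the pair cannot resolve it
    chrom: str
    start: int
    end: int
    left_support: int
    right_support: int

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError("event interval must satisfy start < end")


@dataclass
class InformativeSites:
    """Informative-marker scaffold for one (family, target parent, chromosome).

    ``marker_idx`` are indices into the chromosome's marker slice (strictly
    increasing); ``bp`` the matching 1-based positions; ``codes`` has one row
    per child with the transmitted-allele code (0/1) or UNDETERMINED.
    """

    marker_idx: np.ndarray
    bp: np.ndarray
    children: list[str]
    codes: np.ndarray  # (n_children, n_sites)


def find_informative_sites(parent_dose: np.ndarray, other_dose: np.ndarray,
                           child_doses: np.ndarray, bp: np.ndarray,
                           children: list[str]) -> InformativeSites:
    """Identify informative sites and per-child transmitted-allele codes.

    A site is informative when the target parent is heterozygous (dosage 1)
    and the other parent homozygous (0 or 2), both genotyped.  The code a
    child received from the target parent is ``child - other/2``; values
    outside {0, 1} (Mendelian inconsistency) or missing child genotypes leave
    that child undetermined at the site.
    """
    informative = (parent_dose == 1) & ((other_dose == 0) | (other_dose == 2))
    idx = np.flatnonzero(informative)
    other = other_dose[idx] // 2  # 0 or 1
    codes = np.full((len(children), idx.size), UNDETERMINED, dtype=np.int8)
    for i in range(len(children)):
        cd = child_doses[i, idx]
        code = cd - other
        ok = (cd != MISSING) & ((code == 0) | (code == 1))
        codes[i, ok] = code[ok]
    return InformativeSites(idx, bp[idx], list(children), codes)


def sharing_states(ref_codes: np.ndarray, sib_codes: np.ndarray,
                   bp: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Binary identity-by-state sequence over sites where both sibs are determined.

    Returns (states, positions): state 1 means the pair received the same
    parental allele at that site.
    """
    usable = (ref_codes != UNDETERMINED) & (sib_codes != UNDETERMINED)
    states = (ref_codes[usable] == sib_codes[usable]).astype(np.int8)
    return states, bp[usable]


def _runs(states: np.ndarray) -> list[tuple[int, int]]:
    """Run-length segmentation: list of (start, stop) index pairs."""
    if states.size == 0:
        return []
    bounds = np.flatnonzero(np.diff(states) != 0) + 1
    edges = np.concatenate([[0], bounds, [states.size]])
    return [(int(a), int(b)) for a, b in zip(edges[:-1], edges[1:])]


def call_events_pair(states: np.ndarray, site_bps: np.ndarray,
                     min_run: int = 5) -> list[tuple[int, int, int, int]]:
    """Call switch events from one sharing sequence.

    Runs shorter than ``min_run`` are removed (flanking runs of equal state
    merge), iterating left-to-right to a fixed point; every surviving state
    change becomes one event ``(start, end, left_support, right_support)``
    with the interval bounded by the flanking informative markers in 0-based
    half-open coordinates.
    """
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    states = np.asarray(states)
    site_bps = np.asarray(site_bps)
    if states.size != site_bps.size:
        raise ValueError("states and positions must align")
    if states.size < 2:
        return []
    while True:
        runs = _runs(states)
        if len(runs) <= 1:
            return []
        short = next(((a, b) for a, b in runs if b - a < min_run), None)
        if short is None:
            break
        keep = np.ones(states.size, dtype=bool)
        keep[short[0]:short[1]] = False
        states, site_bps = states[keep], site_bps[keep]
    events = []
    for (la, lb), (ra, rb) in zip(runs[:-1], runs[1:]):
        left_bp = int(site_bps[lb - 1])
        right_bp = int(site_bps[ra])
        events.append((left_bp - 1, right_bp, lb - la, rb - ra))
    return events


def consolidate_family(pair_events: dict[str, list[tuple[int, int, int, int]]],
                       parent: str, chrom: str, ref_child: str,
                       siblings: list[str]) -> list[CrossoverEvent]:
    """Resolve events seen across (reference, sibling) pairs into parent events.

    An interval cluster present in every pair is one crossover in the
    reference child's meiosis (interval = intersection).  A cluster from a
    single pair is a crossover in that sibling's meiosis.  Partial-overlap
    clusters (more than one but not all pairs) count once with ambiguous
    attribution.  With a single pair every event counts once, attribution
    ambiguous between the two children.
    """
    k_minus_1 = len(siblings)
    out: list[CrossoverEvent] = []
    if k_minus_1 == 1:
        sib = siblings[0]
        tag = f"{ref_child}|{sib}"
        for s, e, ls, rs in pair_events.get(sib, []):
            out.append(CrossoverEvent(parent, tag, chrom, s, e, ls, rs))
        return out

    tagged = sorted(((s, e, ls, rs, sib)
                     for sib in siblings
                     for s, e, ls, rs in pair_events.get(sib, [])),
                    key=lambda t: (t[0], t[1]))
    cluster: list[tuple[int, int, int, int, str]] = []
    cur_start = cur_end = None

    def flush():
        if not cluster:
            return
        sibs_seen = {t[4] for t in cluster}
        ls = min(t[2] for t in cluster)
        rs = min(t[3] for t in cluster)
        if len(sibs_seen) == k_minus_1:
            meiosis = ref_child
        elif len(sibs_seen) == 1 and len(cluster) == 1:
            meiosis = cluster[0][4]
        else:
            meiosis = "|".join(sorted(sibs_seen))
        out.append(CrossoverEvent(parent, meiosis, chrom,
                                  int(cur_start), int(cur_end), ls, rs))

    for ev in tagged:
        s, e = ev[0], ev[1]
        if cluster and s < cur_end:
            cur_start, cur_end = max(cur_start, s), min(cur_end, e)
            cluster.append(ev)
        else:
            flush()
            cluster, cur_start, cur_end = [ev], s, e
    flush()
    return out


def call_family_parent(parent_dose, other_dose, child_doses, bp, parent: str,
                       chrom: str, children: list[str],
                       min_run: int = 5) -> list[CrossoverEvent]:
    """Run the full scan for one (family, parent, chromosome)."""
    sites = find_informative_sites(parent_dose, other_dose, child_doses, bp, children)
    ref, sibs = children[0], children[1:]
    pair_events: dict[str, list] = {}
    for j, sib in enumerate(sibs, start=1):
        states, pos = sharing_states(sites.codes[0], sites.codes[j], sites.bp)
        evs = call_events_pair(states, pos, min_run)
        if evs:
            pair_events[sib] = evs
    return consolidate_family(pair_events, parent, chrom, ref, sibs)


def call_cohort(pedigree: Pedigree, marker_map: MarkerMap, genos: GenotypeTable,
                min_run: int = 5) -> pd.DataFrame:
    """Call crossover events for every parent in the cohort.

    Returns a table with columns parent, meiosis, chrom, start, end,
    left_support, right_support.  The reference child is the first listed
    child of each family; families with fewer than two genotyped children are
    skipped with a warning.
    """
    rows = []
    chrom_slices = [(c, marker_map.chrom_slice(c)) for c in marker_map.chromosomes]
    bp_all = marker_map.df["bp"].to_numpy()
    for fam in pedigree.families:
        kids = [c for c in fam.children if genos.has(c)]
        if len(kids) < 2:
            warnings.warn(f"family {fam.fid}: fewer than 2 genotyped children; skipped")
            continue
        if not (genos.has(fam.father) and genos.has(fam.mother)):
            warnings.warn(f"family {fam.fid}: missing parent genotypes; skipped")
            continue
        father_dose = genos.row(fam.father)
        mother_dose = genos.row(fam.mother)
        child_doses = genos.subset_rows(kids)
        for parent, pdose, odose in ((fam.father, father_dose, mother_dose),
                                     (fam.mother, mother_dose, father_dose)):
            for chrom, sl in chrom_slices:
                events = call_family_parent(
                    pdose[sl], odose[sl], child_doses[:, sl], bp_all[sl],
                    parent, chrom, kids, min_run)
                rows.extend((e.parent, e.meiosis, e.chrom, e.start, e.end,
                             e.left_support, e.right_support) for e in events)
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def events_to_bed(events: pd.DataFrame, path) -> str:
    """Export event uncertainty intervals as BED (name = parent:meiosis)."""
    with open(path, "w") as fh:
        for r in events.itertuples():
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.parent}:{r.meiosis}\n")
    return str(path)
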