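"""Per-parent recombination phenotypes from called events and interval tracks.

Five quantitative phenotypes per parent:

* ``ARC``      events per meiosis (all events / number of children),
* ``HS_CNT``   hotspot-overlapping events per meiosis,
* ``NHS_CNT``  non-hotspot events per meiosis,
* ``HS_PCT``   hotspot fraction, HS_CNT / (HS_CNT + NHS_CNT),
* ``MOTIF``    fraction of all events overlapping the motif track.

Because an event is only localised to the interval between its flanking
informative markers, the three hotspot phenotypes are restricted to events
whose uncertainty interval is at most ``resolution_bp`` (default 30 kb) wide;
the filter applies to both numerator and denominator of HS_PCT so the
identity HS_PCT = HS_CNT/(HS_CNT+NHS_CNT) holds exactly.  MOTIF uses all
events.  Phenotypes with a zero denominator are reported missing (NaN).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .io_formats import IntervalTrack, Pedigree, SEX_FEMALE, SEX_MALE

PHENOTYPE_COLUMNS = ["parent", "sex", "cohort", "k",
                     "ARC", "HS_PCT", "HS_CNT", "NHS_CNT", "MOTIF"]
PHENOTYPE_NAMES = ["ARC", "HS_PCT", "HS_CNT", "NHS_CNT", "MOTIF"]

DEFAULT_RESOLUTION_BP = 30_000


def event_overlaps(chrom: str, start: int, end: int, track: IntervalTrack) -> bool:
    """True iff the event interval intersects any track interval by >=1 bp."""
    return track.overlaps(chrom, start, end)


def compute_parent_phenotypes(events: pd.DataFrame, k: int,
                              hotspots: IntervalTrack, motifs: IntervalTrack,
                              resolution_bp: int = DEFAULT_RESOLUTION_BP,
                              motif_window: int = 0) -> dict:
    """Compute the five phenotypes for one parent's events.

    ``events`` holds that parent's rows (chrom/start/end); ``k`` is the
    number of genotyped children.  ``motif_window`` widens motif intervals by
    that many bp on each side before testing overlap ("near the motif").
    """
    if k < 1:
        raise ValueError("a parent needs at least one scored child")
    n_total = len(events)
    out = {"k": k, "ARC": n_total / k}
    motif_track = motifs.expand(motif_window)
    if n_total:
        chroms = events["chrom"].astype(str).to_numpy()
        starts = events["start"].to_numpy()
        ends = events["end"].to_numpy()
        hs_hit = np.array([hotspots.overlaps(c, s, e)
                           for c, s, e in zip(chroms, starts, ends)])
        mot_hit = np.array([motif_track.overlaps(c, s, e)
                            for c, s, e in zip(chroms, starts, ends)])
        narrow = (ends - starts) <= resolution_bp
        n_res = int(narrow.sum())
        n_hs = int((narrow & hs_hit).sum())
        out["HS_CNT"] = n_hs / k
        out["NHS_CNT"] = (n_res - n_hs) / k
        out["HS_PCT"] = n_hs / n_res if n_res else np.nan
        out["MOTIF"] = float(mot_hit.sum()) / n_total
    else:
        out.update(HS_CNT=0.0, NHS_CNT=0.0, HS_PCT=np.nan, MOTIF=np.nan)
    return out


def build_phenotype_table(events: pd.DataFrame, pedigree: Pedigree,
                          hotspots: IntervalTrack, motifs: IntervalTrack,
                          resolution_bp: int = DEFAULT_RESOLUTION_BP,
                          motif_window: int = 0,
                          cohort: str = "sim",
                          genotyped=None) -> pd.DataFrame:
    """One phenotype record per parent with >=2 genotyped children.

    ``genotyped`` optionally restricts which children count toward ``k``
    (defaults to all pedigree children).  Parents of unknown sex are kept in
    the table with a warning; the GWAS layer excludes them from sex strata.
    """
    by_parent = dict(tuple(events.groupby("parent"))) if len(events) else {}
    empty = events.iloc[0:0]
    rows = []
    for fam in pedigree.families:
        kids = [c for c in fam.children if genotyped is None or genotyped(c)]
        if len(kids) < 2:
            continue
        for parent in fam.parents:
            sex = pedigree.sex_of(parent)
            if sex not in (SEX_MALE, SEX_FEMALE):
                warnings.warn(f"parent {parent}: unknown sex; excluded from "
                              "sex-stratified analyses")
            rec = compute_parent_phenotypes(
                by_parent.get(parent, empty), len(kids),
                hotspots, motifs, resolution_bp, motif_window)
            rows.append({"parent": parent, "sex": sex or "0", "cohort": cohort, **rec})
    return pd.DataFrame(rows, columns=PHENOTYPE_COLUMNS)
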