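"""Reference-agnostic multi-context peak orthology.

Peaks from each species are projected into every species' genome via
liftover interval maps.  Raw liftover output is fragmented, so intervals
from the same source peak within 100 bp of each other (nearest end to
nearest end) are merged into their spanning union, and only intervals that
reciprocally re-map to within 100 bp of the original peak are kept.  A peak
within 100 bp of another species' peak (or its mapped location) in any
genome context is conserved; a peak never within 100 bp of another species'
peak in any context — and with exactly one orthologous location in each
other species — is species-specific; everything else is excluded as
ambiguous.  All "within" comparisons are inclusive (≤).
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


def nearest_end_distance(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """0 for overlapping intervals, else the gap between nearest ends."""
    if a_start < b_end and b_start < a_end:
        return 0
    return max(b_start - a_end, a_start - b_end)


@dataclasses.dataclass
class OrthologyCall:
    peak_id: str
    species: str
    status: str                       # conserved | species_specific | ambiguous_excluded
    associated_species: frozenset     # species whose peaks this peak associates with
    n_ortholog_locations: dict[str, int]


# ---------------------------------------------------------------------------
# interval plumbing


def merge_mapped(intervals: pd.DataFrame, gap: int = 100) -> pd.DataFrame:
    """Single-linkage merge of mapped intervals per (peak_id, dst context).

    Input columns: peak_id, dst_chrom, dst_start, dst_end (src columns pass
    through ignored).  Intervals from the same peak within ``gap`` bp
    (nearest end to nearest end, inclusive) merge transitively into their
    spanning union.
    """
    if not len(intervals):
        return pd.DataFrame(columns=["peak_id", "dst_chrom", "dst_start", "dst_end"])
    rows = []
    for (pid, chrom), grp in intervals.groupby(["peak_id", "dst_chrom"], sort=False):
        g = grp.sort_values(["dst_start", "dst_end"])
        cur_s, cur_e = None, None
        for r in g.itertuples():
            if cur_s is None:
                cur_s, cur_e = r.dst_start, r.dst_end
            elif r.dst_start - cur_e <= gap:   # sorted ⇒ nearest-end distance
                cur_e = max(cur_e, r.dst_end)
            else:
                rows.append((pid, chrom, cur_s, cur_e))
                cur_s, cur_e = r.dst_start, r.dst_end
        rows.append((pid, chrom, cur_s, cur_e))
    return pd.DataFrame(rows, columns=["peak_id", "dst_chrom", "dst_start", "dst_end"])


def reciprocal_filter(merged_forward: pd.DataFrame, back_mapped: pd.DataFrame,
                      original_peaks: pd.DataFrame, tol: int = 100) -> pd.DataFrame:
    """Keep forward-mapped intervals whose back-map lands within ``tol`` bp
    of the original peak (nearest-end, inclusive; 0 when overlapping).

    ``back_mapped`` must already be merged with the same pipeline in the
    source context; peaks with no back-map record are dropped and logged.
    """
    orig = original_peaks.set_index("peak_id")
    back = {pid: grp for pid, grp in back_mapped.groupby("peak_id", sort=False)}
    keep = []
    n_missing = 0
    for r in merged_forward.itertuples():
        grp = back.get(r.peak_id)
        if grp is None or r.peak_id not in orig.index:
            n_missing += 1
            keep.append(False)
            continue
        o = orig.loc[r.peak_id]
        keep.append(any(
            b.dst_chrom == o.chrom and nearest_end_distance(
                int(b.dst_start), int(b.dst_end), int(o.start), int(o.end)) <= tol
            for b in grp.itertuples()))
    if n_missing:
        log.info("reciprocal_filter: %d intervals lacked a back-map record", n_missing)
    return merged_forward.loc[np.asarray(keep, dtype=bool)].reset_index(drop=True)


# ---------------------------------------------------------------------------
# orthology classification


def classify_orthology(
    peak_sets: dict[str, pd.DataFrame],
    ortholog_locations: dict[tuple[str, str], pd.DataFrame],
    proximity: int = 100,
) -> list[OrthologyCall]:
    """Call every peak conserved / species-specific / ambiguous.

    ``peak_sets``: species -> DataFrame(chrom,start,end,peak_id) of native
    peaks.  ``ortholog_locations``: (species, context) -> merged+filtered
    mapped intervals of that species' peaks in ``context``'s genome
    (columns peak_id, dst_chrom, dst_start, dst_end).
    """
    species = list(peak_sets)
    if len(species) < 2:
        raise ValueError("orthology needs at least two species")

    # location of every peak in every context: native coords in its own
    # genome, mapped coords elsewhere
    def locations(sp: str, ctx: str) -> pd.DataFrame:
        if sp == ctx:
            return peak_sets[sp][["chrom", "start", "end", "peak_id"]]
        m = ortholog_locations.get((sp, ctx))
        if m is None or not len(m):
            return pd.DataFrame(columns=["chrom", "start", "end", "peak_id"])
        return m.rename(columns={"dst_chrom": "chrom", "dst_start": "start",
                                 "dst_end": "end"})[["chrom", "start", "end", "peak_id"]]

    # index everything once: per-peak interval lists and per-chromosome
    # target arrays, so the per-peak loop is dictionary lookups + vector ops
    by_peak: dict[tuple, dict] = {}
    by_chrom: dict[tuple, dict] = {}
    for sp in species:
        for ctx in species:
            df = locations(sp, ctx)
            d: dict[str, list] = {}
            for r in df.itertuples():
                d.setdefault(r.peak_id, []).append((r.chrom, int(r.start), int(r.end)))
            by_peak[(sp, ctx)] = d
            by_chrom[(sp, ctx)] = {
                chrom: (grp["start"].to_numpy(), grp["end"].to_numpy())
                for chrom, grp in df.groupby("chrom", sort=False)
            } if len(df) else {}

    def associated_anywhere(intervals, target_key) -> bool:
        targets = by_chrom[target_key]
        for chrom, start, end in intervals:
            arrs = targets.get(chrom)
            if arrs is None:
                continue
            s, e = arrs
            gap = np.where((s < end) & (start < e), 0,
                           np.maximum(s - end, start - e))
            if (gap <= proximity).any():
                return True
        return False

    calls: list[OrthologyCall] = []
    for sp in species:
        others = [o for o in species if o != sp]
        for r in peak_sets[sp].itertuples():
            counts = {o: len(by_peak[(sp, o)].get(r.peak_id, ())) for o in others}
            if any(c == 0 for c in counts.values()):
                calls.append(OrthologyCall(r.peak_id, sp, "ambiguous_excluded",
                                           frozenset(), counts))
                continue
            associated = set()
            for ctx in species:
                mine = by_peak[(sp, ctx)].get(r.peak_id)
                if not mine:
                    continue
                for o in others:
                    if o not in associated and associated_anywhere(mine, (o, ctx)):
                        associated.add(o)
            if associated:
                status = "conserved"
            elif all(c == 1 for c in counts.values()):
                status = "species_specific"
            else:
                status = "ambiguous_excluded"
            calls.append(OrthologyCall(r.peak_id, sp, status,
                                       frozenset(associated), counts))
    return calls


def conservation_summary(calls: list[OrthologyCall]) -> pd.DataFrame:
    """Per-species counts and fractions of each orthology status."""
    df = pd.DataFrame([{"species": c.species, "status": c.status} for c in calls])
    rows = []
    for sp, grp in df.groupby("species"):
        counts = grp["status"].value_counts()
        total = int(counts.sum())
        classified = int(counts.get("conserved", 0) + counts.get("species_specific", 0))
        rows.append({
            "species": sp,
            "n_total": total,
            "n_conserved": int(counts.get("conserved", 0)),
            "n_specific": int(counts.get("species_specific", 0)),
            "n_ambiguous": int(counts.get("ambiguous_excluded", 0)),
            "frac_conserved": counts.get("conserved", 0) / classified if classified else np.nan,
            "frac_specific": counts.get("species_specific", 0) / classified if classified else np.nan,
        })
    return pd.DataFrame(rows)


def species_specific_loss_calls(calls: list[OrthologyCall],
                                phylogeny: tuple = (("mel", "sim"), "yak")) -> pd.DataFrame:
    """Assign lineage-specific losses by parsimony on a ((in1,in2),out) tree.

    An outgroup peak associated with exactly one ingroup species implies a
    loss on the lineage of the other ingroup; outgroup-only absence is left
    uncalled (the ancestral state is not inferable).
    """
    (in1, in2), out = phylogeny
    rows = []
    for c in calls:
        if c.species != out or c.status == "ambiguous_excluded":
            continue
        has1, has2 = in1 in c.associated_species, in2 in c.associated_species
        if has1 != has2:
            rows.append({"peak_id": c.peak_id,
                         "lost_in": in2 if has1 else in1,
                         "retained_in": in1 if has1 else in2})
    return pd.DataFrame(rows, columns=["peak_id", "lost_in", "retained_in"])
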