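"""Example construction: genomes + called peaks -> one-hot training data.

Coordinates are 0-based half-open (BED convention) throughout.  Positive
examples are fixed-length windows centred on the midpoint of tissue-merged
peaks; negative examples are non-overlapping genome tiles that touch no
merged peak.  Chromosome "3L" is held out for testing by default and a
seeded uniform 10% of the remainder forms the validation split.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

BASE_ORDER = "ACGT"
_ENCODE_LUT = np.zeros((256, 4), dtype=np.uint8)
for _i, _b in enumerate(BASE_ORDER):
    _ENCODE_LUT[ord(_b), _i] = 1
    _ENCODE_LUT[ord(_b.lower()), _i] = 1
_VALID = np.zeros(256, dtype=bool)
for _b in BASE_ORDER + BASE_ORDER.lower() + "Nn":
    _VALID[ord(_b)] = True


@dataclasses.dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (self.chrom == other.chrom
                and self.start < other.end and other.start < self.end)


@dataclasses.dataclass
class EncodedExample:
    seq: np.ndarray                # (4, L) one-hot, uint8
    labels: dict[str, int]
    origin: GenomicInterval
    split: str = ""


@dataclasses.dataclass
class ExampleSet:
    """Columnar example store: X (n, 4, L) uint8, y (n, n_tissues)."""

    X: np.ndarray
    y: np.ndarray
    origins: pd.DataFrame          # chrom,start,end
    tissues: tuple[str, ...]
    split: np.ndarray | None = None  # per-example {train,val,test}
    provenance: str = ""

    def __len__(self):
        return len(self.X)

    def subset(self, mask: np.ndarray) -> "ExampleSet":
        idx = np.flatnonzero(mask) if mask.dtype == bool else np.asarray(mask)
        return ExampleSet(self.X[idx], self.y[idx],
                          self.origins.iloc[idx].reset_index(drop=True), self.tissues,
                          None if self.split is None else self.split[idx],
                          self.provenance)

    def split_sets(self):
        """(train, val, test) as (X, y) pairs plus the index masks."""
        out = {}
        for name in ("train", "val", "test"):
            mask = self.split == name
            out[name] = (self.X[mask], self.y[mask])
        return out


# ---------------------------------------------------------------------------
# one-hot


def one_hot(seq: str) -> np.ndarray:
    """Encode a base string as a (4, L) matrix, channel order A,C,G,T.

    N encodes as an all-zero column; other characters raise with position.
    """
    raw = np.frombuffer(seq.encode(), dtype=np.uint8)
    bad = ~_VALID[raw]
    if bad.any():
        pos = int(np.argmax(bad))
        raise ValueError(f"invalid base {seq[pos]!r} at position {pos}")
    return _ENCODE_LUT[raw].T.copy()


def decode_one_hot(mat: np.ndarray) -> str:
    """Inverse of :func:`one_hot`; zero columns decode to N."""
    mat = np.asarray(mat)
    hot = mat.sum(axis=0)
    idx = mat.argmax(axis=0)
    chars = np.frombuffer(BASE_ORDER.encode(), dtype=np.uint8)[idx]
    chars = np.where(hot == 0, ord("N"), chars).astype(np.uint8)
    return chars.tobytes().decode()


# ---------------------------------------------------------------------------
# peak merging


def merge_tissue_peaks(peaks_by_tissue: dict[str, list[tuple]]) -> pd.DataFrame:
    """Merge overlapping peaks across tissues into single flagged intervals.

    Input: tissue -> list of (chrom, start, end).  Output rows are pairwise
    non-overlapping, with one boolean column per tissue set iff the merged
    interval overlaps at least one input peak of that tissue (>=1 bp).
    """
    tissues = list(peaks_by_tissue)
    records = []
    for t in tissues:
        for iv in peaks_by_tissue[t]:
            chrom, start, end = iv[0], int(iv[1]), int(iv[2])
            if start >= end:
                raise ValueError(f"invalid interval {chrom}:{start}-{end}")
            records.append((chrom, start, end, t))
    rows = []
    df = pd.DataFrame(records, columns=["chrom", "start", "end", "tissue"])
    for chrom, grp in df.groupby("chrom", sort=True):
        grp = grp.sort_values(["start", "end"]).reset_index(drop=True)
        cur_start, cur_end, members = None, None, set()
        for r in grp.itertuples():
            if cur_start is None or r.start >= cur_end:
                if cur_start is not None:
                    rows.append((chrom, cur_start, cur_end, frozenset(members)))
                cur_start, cur_end, members = r.start, r.end, {r.tissue}
            else:
                cur_end = max(cur_end, r.end)
                members.add(r.tissue)
        if cur_start is not None:
            rows.append((chrom, cur_start, cur_end, frozenset(members)))
    out = pd.DataFrame(rows, columns=["chrom", "start", "end", "members"])
    for t in tissues:
        out[t] = out["members"].map(lambda m: int(t in m))
    return out.drop(columns="members")


# ---------------------------------------------------------------------------
# example builders


def _fetch(genome, chrom: str, start: int, end: int) -> str:
    """Sequence access over pyfaidx.Fasta or a plain {chrom: str} mapping."""
    if chrom not in genome:
        raise KeyError(f"chromosome {chrom!r} not present in genome")
    seq = genome[chrom]
    if hasattr(seq, "seq") or not isinstance(seq, str):
        frag = seq[start:end]
        return str(frag.seq if hasattr(frag, "seq") else frag)
    return seq[start:end]


def _chrom_length(genome, chrom: str) -> int:
    return len(genome[chrom])


def build_positive_examples(merged: pd.DataFrame, genome, tissues,
                            flank: int = 500, max_n_frac: float = 0.1):
    """One example per merged peak: midpoint ± flank, labels from flags.

    Peaks whose window leaves the chromosome and examples with more than
    ``max_n_frac`` ambiguous bases are dropped (counted, logged).
    """
    examples, dropped = [], {"bounds": 0, "n_frac": 0}
    rows = []
    for r in merged.itertuples():
        mid = (r.start + r.end) // 2
        start, end = mid - flank, mid + flank
        if start < 0 or end > _chrom_length(genome, r.chrom):
            dropped["bounds"] += 1
            continue
        seq = _fetch(genome, r.chrom, start, end)
        oh = one_hot(seq)
        if (oh.sum(axis=0) == 0).mean() > max_n_frac:
            dropped["n_frac"] += 1
            continue
        examples.append(oh)
        rows.append({"chrom": r.chrom, "start": start, "end": end,
                     **{t: getattr(r, t) for t in tissues}})
    if dropped["bounds"] or dropped["n_frac"]:
        log.info("dropped positive examples: %s", dropped)
    origins = pd.DataFrame(rows, columns=["chrom", "start", "end", *tissues])
    X = np.stack(examples) if examples else np.empty((0, 4, 2 * flank), dtype=np.uint8)
    y = origins[list(tissues)].to_numpy() if len(origins) else np.empty((0, len(tissues)))
    return X, y.astype(np.int8), origins[["chrom", "start", "end"]], dropped


def build_negative_examples(genome, merged: pd.DataFrame, tissues,
                            tile: int = 1000, max_n_frac: float = 0.1):
    """Non-overlapping tiles at stride = tile; tiles touching any merged
    peak by >=1 bp are excluded; trailing partial tiles are dropped."""
    if tile <= 0:
        raise ValueError("tile must be positive")
    examples, rows = [], []
    n_dropped = 0
    chroms = list(genome.keys()) if hasattr(genome, "keys") else [c.name for c in genome]
    for chrom in chroms:
        L = _chrom_length(genome, chrom)
        peaks = merged[merged.chrom == chrom]
        starts = peaks["start"].to_numpy()
        ends = peaks["end"].to_numpy()
        for t0 in range(0, L - tile + 1, tile):
            t1 = t0 + tile
            if ((starts < t1) & (t0 < ends)).any():
                continue
            oh = one_hot(_fetch(genome, chrom, t0, t1))
            if (oh.sum(axis=0) == 0).mean() > max_n_frac:
                n_dropped += 1
                continue
            examples.append(oh)
            rows.append({"chrom": chrom, "start": t0, "end": t1})
    if n_dropped:
        log.info("dropped %d high-N negative tiles", n_dropped)
    origins = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    X = np.stack(examples) if examples else np.empty((0, 4, tile), dtype=np.uint8)
    y = np.zeros((len(X), len(tissues)), dtype=np.int8)
    return X, y, origins


def proximal_negative_subset(neg_origins: pd.DataFrame, pos_origins: pd.DataFrame,
                             max_gap: int = 500) -> np.ndarray:
    """Mask of negatives whose nearest peak-example edge is <= max_gap away.

    Distance is nearest-end to nearest-end, 0 for overlap (overlap cannot
    occur for tiles that survived peak exclusion, but the rule is general).
    """
    keep = np.zeros(len(neg_origins), dtype=bool)
    for chrom, grp in neg_origins.groupby("chrom"):
        pos = pos_origins[pos_origins.chrom == chrom]
        if not len(pos):
            continue
        ps = pos["start"].to_numpy()
        pe = pos["end"].to_numpy()
        for i, r in zip(grp.index, grp.itertuples()):
            gap = np.where((ps < r.end) & (r.start < pe), 0,
                           np.maximum(ps - r.end, r.start - pe))
            keep[i] = gap.min() <= max_gap
    return keep


def split_examples(X, y, origins: pd.DataFrame, tissues,
                   test_chrom: str = "3L", val_frac: float = 0.1,
                   seed: int = 0) -> ExampleSet:
    """Chromosome-holdout test split + seeded uniform validation subset.

    |val| = floor(val_frac * n_non_test); train is the remainder.
    """
    chroms = origins["chrom"].to_numpy()
    if test_chrom not in set(chroms):
        raise ValueError(f"test chromosome {test_chrom!r} absent from examples")
    split = np.full(len(origins), "train", dtype=object)
    test_mask = chroms == test_chrom
    split[test_mask] = "test"
    rest = np.flatnonzero(~test_mask)
    if len(rest) == 0:
        log.warning("all examples are on the test chromosome; train set is empty")
    rng = np.random.default_rng(seed)
    n_val = int(np.floor(val_frac * len(rest)))
    val_idx = rng.choice(rest, size=n_val, replace=False)
    split[val_idx] = "val"
    prov = hashlib.sha256(
        f"{test_chrom}|{val_frac}|{seed}|{len(origins)}".encode()).hexdigest()[:12]
    return ExampleSet(X=X, y=np.asarray(y), origins=origins.reset_index(drop=True),
                      tissues=tuple(tissues), split=split.astype("U5"), provenance=prov)


def build_example_set(genome, peaks_by_tissue: dict[str, list[tuple]],
                      flank: int = 500, tile: int = 1000,
                      test_chrom: str = "3L", val_frac: float = 0.1,
                      seed: int = 0) -> ExampleSet:
    """Full pipeline: merge peaks, build positives + negatives, split."""
    tissues = tuple(peaks_by_tissue)
    merged = merge_tissue_peaks(peaks_by_tissue)
    Xp, yp, op, _ = build_positive_examples(merged, genome, tissues, flank=flank)
    Xn, yn, on = build_negative_examples(genome, merged, tissues, tile=tile)
    X = np.concatenate([Xp, Xn]) if len(Xp) or len(Xn) else Xp
    y = np.concatenate([yp, yn])
    origins = pd.concat([op, on], ignore_index=True)
    origins["is_peak"] = np.r_[np.ones(len(op), dtype=int), np.zeros(len(on), dtype=int)]
    return split_examples(X, y, origins, tissues, test_chrom=test_chrom,
                          val_frac=val_frac, seed=seed)


def save_manifest(es: ExampleSet, path: str | Path) -> None:
    df = es.origins.copy()
    for j, t in enumerate(es.tissues):
        df[t] = es.y[:, j]
    df["split"] = es.split
    df.to_csv(path, sep="\t", index=False)
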