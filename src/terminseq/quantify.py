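"""Fragment counting over genes and gene halves, coverage tracks, normalization.

Aligned fragments (the outer span of a read pair on the genome, with the
strand of the originating RNA after library-protocol decoding) are assigned
to regions by their *biological 5'-most base*: for a region on the + strand
that is the fragment's lowest coordinate, on the - strand the highest. The
rule is gene-strand-aware, so a fragment straddling the bisection midpoint
is counted in exactly one half, and for fragments fully inside a gene the
half counts always sum to the whole-gene count.

Fragments live in a pandas DataFrame with columns
``chrom, start, end, strand, sample_id`` (0-based half-open). Counts are
held in a :class:`CountMatrix` together with the sample sheet describing
genotype x condition x replicate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .gene_models import GeneModel, HalfRegion

__all__ = [
    "FRAGMENT_COLUMNS",
    "CountMatrix",
    "read_fragments",
    "write_fragments_bed",
    "read_sample_sheet",
    "validate_sample_sheet",
    "count_fragments",
    "coverage_track",
    "write_bedgraph",
    "size_factors",
]

FRAGMENT_COLUMNS = ["chrom", "start", "end", "strand", "sample_id"]

GENOTYPES = ("WT", "hen2", "exosome_core", "zcchc8ab", "other")
CONDITIONS = ("control_22C", "cold_12h_4C", "other")


def read_fragments(path, fmt: str = "bed") -> pd.DataFrame:
    """Read fragments from 6-column BED (name column = sample_id) or a
    header-carrying TSV with the canonical columns."""
    if fmt == "bed":
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "sample_id", "score", "strand"],
            dtype={"chrom": str, "sample_id": str},
        ).drop(columns="score")
    elif fmt == "tsv":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample_id": str})
    else:
        raise ValueError(f"unknown fragment format {fmt!r}")
    missing = set(FRAGMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing fragment columns {sorted(missing)}")
    if len(df) and not (df["end"] > df["start"]).all():
        raise ValueError(f"{path}: fragments must satisfy end > start")
    return df[FRAGMENT_COLUMNS]


def write_fragments_bed(fragments: pd.DataFrame, path) -> None:
    out = fragments.copy()
    out["score"] = "."
    out[["chrom", "start", "end", "sample_id", "score", "strand"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def validate_sample_sheet(samples: pd.DataFrame) -> pd.DataFrame:
    required = {"sample_id", "genotype", "condition", "replicate"}
    missing = required - set(samples.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns {sorted(missing)}")
    if samples["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in sample sheet")
    key = samples[["genotype", "condition", "replicate"]]
    if key.duplicated().any():
        raise ValueError("duplicate (genotype, condition, replicate) in sample sheet")
    if (samples["replicate"].astype(int) < 1).any():
        raise ValueError("replicate must be >= 1")
    return samples


def read_sample_sheet(path) -> pd.DataFrame:
    return validate_sample_sheet(pd.read_csv(path, sep="\t", dtype={"sample_id": str}))


@dataclass
class CountMatrix:
    """Integer fragment counts for regions x samples, plus sample metadata.

    ``library_sizes`` are the total input fragments per sample (counted or
    not), so column sums never exceed them.
    """

    region_ids: list[str]
    samples: pd.DataFrame
    counts: np.ndarray
    library_sizes: np.ndarray
    report: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.region_ids), len(self.samples)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.region_ids)} regions x {len(self.samples)} samples"
            )
        if self.counts.size and (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if self.counts.size and not np.allclose(self.counts, np.round(self.counts)):
                raise ValueError("counts must be integral")
            self.counts = self.counts.astype(np.int64)
        self.library_sizes = np.asarray(self.library_sizes, dtype=float)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples["sample_id"])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=pd.Index(self.region_ids, name="region_id"),
                            columns=self.sample_ids)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, samples: pd.DataFrame,
                   library_sizes=None) -> "CountMatrix":
        samples = validate_sample_sheet(samples)
        frame = frame[list(samples["sample_id"])]
        if library_sizes is None:
            library_sizes = frame.sum(axis=0).to_numpy(dtype=float)
        return cls(list(frame.index), samples.reset_index(drop=True),
                   frame.to_numpy(), library_sizes)

    @classmethod
    def read_tsv(cls, counts_path, samples_path) -> "CountMatrix":
        frame = pd.read_csv(counts_path, sep="\t", index_col=0)
        frame.columns = frame.columns.astype(str)
        return cls.from_frame(frame, read_sample_sheet(samples_path))

    def subset_samples(self, mask) -> "CountMatrix":
        sub = self.samples.loc[mask].reset_index(drop=True)
        idx = np.flatnonzero(np.asarray(mask))
        return CountMatrix(self.region_ids, sub, self.counts[:, idx],
                           self.library_sizes[idx], dict(self.report))


def _region_id(region) -> str:
    return region.region_id if isinstance(region, HalfRegion) else region.gene_id


def _effective_strand(strand: pd.Series, stranded: str) -> pd.Series:
    if stranded == "reverse":
        return strand.map({"+": "-", "-": "+"})
    return strand


def count_fragments(
    fragments: pd.DataFrame,
    regions: Sequence[HalfRegion | GeneModel],
    samples: pd.DataFrame,
    stranded: str = "yes",
) -> CountMatrix:
    """Count fragments per region and sample by the 5'-anchor rule.

    A fragment is counted in a region iff its biological 5'-most base under
    the *region's* strand lies inside the region and, unless
    ``stranded='no'``, its decoded RNA strand matches the region strand
    (``'reverse'`` flips the stored fragment strand first, for dUTP-style
    protocols). Fragments overlapping several (half-)regions of different
    genes are counted once per qualifying region.
    """
    if stranded not in ("yes", "reverse", "no"):
        raise ValueError(f"unknown strandedness keyword {stranded!r}")
    samples = validate_sample_sheet(samples).reset_index(drop=True)
    region_ids = [_region_id(r) for r in regions]
    if len(set(region_ids)) != len(region_ids):
        raise ValueError("duplicate region ids")

    sample_ids = list(samples["sample_id"])
    sample_index = {s: j for j, s in enumerate(sample_ids)}
    counts = np.zeros((len(regions), len(samples)), dtype=np.int64)
    library_sizes = np.zeros(len(samples), dtype=float)
    region_chroms = {r.chrom for r in regions}
    n_unknown_chrom = 0
    n_counted_hits = 0

    frags = fragments.copy()
    frags["eff_strand"] = _effective_strand(frags["strand"], stranded)

    # per (sample, chrom, eff_strand): sorted anchor arrays for point queries
    anchors: dict[tuple, dict[str, tuple[np.ndarray, np.ndarray]]] = {}
    for (sid, chrom), grp in frags.groupby(["sample_id", "chrom"], sort=False):
        if sid not in sample_index:
            raise ValueError(f"fragment sample_id {sid!r} absent from sample sheet")
        library_sizes[sample_index[sid]] += len(grp)
        if chrom not in region_chroms:
            n_unknown_chrom += len(grp)
            continue
        per_strand = {}
        for s in ("+", "-"):
            sub = grp if stranded == "no" else grp[grp["eff_strand"] == s]
            per_strand[s] = (
                np.sort(sub["start"].to_numpy()),        # anchors for + regions
                np.sort(sub["end"].to_numpy() - 1),      # anchors for - regions
            )
        anchors[(sid, chrom)] = per_strand

    for i, region in enumerate(regions):
        for sid in sample_ids:
            per_strand = anchors.get((sid, region.chrom))
            if per_strand is None:
                continue
            starts_sorted, ends_sorted = per_strand[region.strand]
            arr = starts_sorted if region.strand == "+" else ends_sorted
            n = int(np.searchsorted(arr, region.end, side="left")
                    - np.searchsorted(arr, region.start, side="left"))
            counts[i, sample_index[sid]] = n
            n_counted_hits += n

    report = {
        "n_fragments": int(len(frags)),
        "n_unknown_chrom": n_unknown_chrom,
        "n_region_assignments": n_counted_hits,
    }
    return CountMatrix(region_ids, samples, counts, library_sizes, report)


def coverage_track(
    fragments: pd.DataFrame,
    region: HalfRegion | GeneModel,
    sample_id: str | None = None,
    stranded: str = "no",
) -> np.ndarray:
    """Per-base overlap counts of selected fragments over ``region``.

    Position ``i`` of the returned vector is the number of fragments
    overlapping genomic base ``region.start + i`` (genomic orientation; no
    strand flipping — that is the metaprofile's job).
    """
    if stranded not in ("yes", "reverse", "no"):
        raise ValueError(f"unknown strandedness keyword {stranded!r}")
    L = region.end - region.start
    sel = fragments[fragments["chrom"] == region.chrom]
    if sample_id is not None:
        sel = sel[sel["sample_id"] == sample_id]
    if stranded != "no":
        sel = sel[_effective_strand(sel["strand"], stranded) == region.strand]
    starts = np.clip(sel["start"].to_numpy(dtype=np.int64) - region.start, 0, L)
    ends = np.clip(sel["end"].to_numpy(dtype=np.int64) - region.start, 0, L)
    keep = ends > starts
    delta = np.zeros(L + 1, dtype=np.int64)
    np.add.at(delta, starts[keep], 1)
    np.add.at(delta, ends[keep], -1)
    return np.cumsum(delta[:-1])


def write_bedgraph(coverage: np.ndarray, region, path, append: bool = False) -> None:
    """Write a per-base coverage vector as bedGraph (runs of equal value merged)."""
    cov = np.asarray(coverage)
    mode = "a" if append else "w"
    with open(path, mode) as fh:
        if len(cov) == 0:
            return
        change = np.flatnonzero(np.diff(cov)) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [len(cov)]])
        for s, e in zip(starts, ends):
            v = cov[s]
            if v != 0:
                fh.write(f"{region.chrom}\t{region.start + s}\t{region.start + e}\t{v}\n")


def size_factors(cm: CountMatrix | np.ndarray) -> np.ndarray:
    """Median-of-ratios normalization factors, scaled to geometric mean 1.

    For each sample the factor is the median across all-positive regions of
    ``count / geometric-mean-across-samples``. If no region is positive in
    every sample, falls back to library-size ratios with a warning.
    """
    counts = cm.counts if isinstance(cm, CountMatrix) else np.asarray(cm)
    counts = np.atleast_2d(counts).astype(float)
    n_samples = counts.shape[1]
    if n_samples == 1:
        return np.ones(1)
    positive = (counts > 0).all(axis=1)
    if positive.any():
        sub = counts[positive]
        log_geo = np.mean(np.log(sub), axis=1, keepdims=True)
        factors = np.exp(np.median(np.log(sub) - log_geo, axis=0))
    else:
        warnings.warn("no region with all-positive counts; using library-size factors",
                      stacklevel=2)
        lib = (cm.library_sizes if isinstance(cm, CountMatrix)
               else counts.sum(axis=0))
        lib = np.asarray(lib, dtype=float)
        if (lib <= 0).any():
            raise ValueError("cannot normalize: empty library")
        factors = lib
    return factors / np.exp(np.mean(np.log(factors)))
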