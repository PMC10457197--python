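"""Shared containers and error types for the 5mC/5hmC + nascent-transcription pipeline.

Coordinate convention throughout: 0-based, half-open intervals ``[start, end)``,
matching BED. Beta values live in ``[0, 1]``; count matrices hold non-negative
integers with features on rows and samples on columns.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PipelineError",
    "PlacementError",
    "AlignmentError",
    "ContrastError",
    "ConfigurationError",
    "SampleSheet",
    "BetaMatrix",
    "CountMatrix",
    "GenomeAnnotation",
    "CoverageTracks",
    "read_tsv_matrix",
    "write_tsv_matrix",
]


class PipelineError(Exception):
    """Base class for package errors."""


class PlacementError(PipelineError):
    """Raised when a synthetic feature class cannot be placed in the genome."""


class AlignmentError(PipelineError):
    """Raised when paired matrices disagree on probes or sample design."""


class ContrastError(PipelineError):
    """Raised when a requested condition label is absent from the design."""


class ConfigurationError(PipelineError):
    """Raised for invalid parameter combinations or config files."""


def _check_design(design: pd.DataFrame) -> pd.DataFrame:
    required = {"condition", "replicate"}
    missing = required - set(design.columns)
    if missing:
        raise ConfigurationError(f"sample sheet missing columns: {sorted(missing)}")
    return design


@dataclass
class SampleSheet:
    """Sample design: index = sample id, columns condition and replicate."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        self.table = _check_design(self.table)

    @property
    def samples(self) -> list[str]:
        return list(self.table.index)

    def samples_for(self, condition: str) -> list[str]:
        hit = self.table.index[self.table["condition"] == condition]
        if len(hit) == 0:
            raise ContrastError(f"condition {condition!r} not present in design")
        return list(hit)

    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self.table["condition"]))


@dataclass
class BetaMatrix:
    """Probe x sample methylation beta values for one assay (BS or oxBS)."""

    values: pd.DataFrame
    design: SampleSheet
    assay: str = "BS"

    def __post_init__(self) -> None:
        if list(self.values.columns) != self.design.samples:
            raise AlignmentError(
                "beta matrix columns do not match sample sheet: "
                f"{list(self.values.columns)} vs {self.design.samples}"
            )
        bad = self.values.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            out = np.nansum((bad < 0) | (bad > 1))
        if out:
            raise ValueError(f"{int(out)} beta values outside [0, 1]")

    @property
    def probes(self) -> pd.Index:
        return self.values.index

    def condition_mean(self, condition: str) -> pd.Series:
        return self.values[self.design.samples_for(condition)].mean(axis=1)

    def write(self, path: str | Path) -> None:
        write_tsv_matrix(self.values, path)


@dataclass
class CountMatrix:
    """Feature x sample integer counts plus design, for genes or eRNAs."""

    counts: pd.DataFrame
    design: SampleSheet
    feature_kind: str = "gene"

    def __post_init__(self) -> None:
        if list(self.counts.columns) != self.design.samples:
            raise AlignmentError("count matrix columns do not match sample sheet")
        arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def features(self) -> pd.Index:
        return self.counts.index

    def write(self, path: str | Path) -> None:
        write_tsv_matrix(self.counts, path)


@dataclass
class GenomeAnnotation:
    """Interval features of a (synthetic or real) genome.

    All tables use 0-based half-open coordinates. ``probes`` carries single-bp
    CpG probe positions; ``gene_sets``/``probe_sets`` hold named id lists
    (e.g. the HLA-like cluster).
    """

    chromosomes: pd.DataFrame  # chrom, length
    genes: pd.DataFrame  # id, chrom, start, end, strand
    promoters: pd.DataFrame  # gene_id, chrom, start, end, strand
    enhancers: pd.DataFrame  # id, chrom, start, end
    cpg_islands: pd.DataFrame  # id, chrom, start, end
    probes: pd.DataFrame  # id, chrom, pos
    gene_sets: dict[str, list[str]] = field(default_factory=dict)
    probe_sets: dict[str, list[str]] = field(default_factory=dict)

    def chrom_length(self, chrom: str) -> int:
        row = self.chromosomes.loc[self.chromosomes["chrom"] == chrom, "length"]
        if row.empty:
            raise KeyError(f"unknown chromosome {chrom!r}")
        return int(row.iloc[0])

    def tss(self) -> pd.DataFrame:
        """Strand-aware transcription start sites, one row per gene."""
        g = self.genes
        pos = np.where(g["strand"] == "+", g["start"], g["end"] - 1)
        return pd.DataFrame({"id": g["id"], "chrom": g["chrom"], "tss": pos})

    def write_bed(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.chromosomes.to_csv(outdir / "chromosomes.tsv", sep="\t",
                                index=False)
        for name, df, id_col, strand in (
            ("genes", self.genes, "id", True),
            ("promoters", self.promoters, "gene_id", True),
            ("enhancers", self.enhancers, "id", False),
            ("cpg_islands", self.cpg_islands, "id", False),
        ):
            bed = pd.DataFrame(
                {
                    "chrom": df["chrom"],
                    "start": df["start"],
                    "end": df["end"],
                    "name": df[id_col],
                    "score": 0,
                    "strand": df["strand"] if strand else ".",
                }
            )
            bed.to_csv(outdir / f"{name}.bed", sep="\t", header=False, index=False)
        probes = pd.DataFrame(
            {
                "chrom": self.probes["chrom"],
                "start": self.probes["pos"],
                "end": self.probes["pos"] + 1,
                "name": self.probes["id"],
                "score": 0,
                "strand": ".",
            }
        )
        probes.to_csv(outdir / "probes.bed", sep="\t", header=False, index=False)
        rows = [(n, m) for n, ids in sorted(self.gene_sets.items()) for m in ids]
        pd.DataFrame(rows, columns=["set", "gene_id"]).to_csv(
            outdir / "gene_sets.tsv", sep="\t", index=False
        )
        rows = [(n, m) for n, ids in sorted(self.probe_sets.items()) for m in ids]
        pd.DataFrame(rows, columns=["set", "probe_id"]).to_csv(
            outdir / "probe_sets.tsv", sep="\t", index=False
        )


@dataclass
class CoverageTracks:
    """Strand-specific binned coverage, keyed by (sample, chrom, strand)."""

    bin_size: int
    chrom_lengths: dict[str, int]
    data: dict[tuple[str, str, str], np.ndarray]

    @property
    def samples(self) -> list[str]:
        return sorted({k[0] for k in self.data})

    def n_bins(self, chrom: str) -> int:
        return -(-self.chrom_lengths[chrom] // self.bin_size)

    def pooled(self) -> dict[tuple[str, str], np.ndarray]:
        """Sum coverage over samples, keyed by (chrom, strand)."""
        out: dict[tuple[str, str], np.ndarray] = {}
        for (_, chrom, strand), arr in self.data.items():
            key = (chrom, strand)
            if key in out:
                out[key] = out[key] + arr
            else:
                out[key] = arr.astype(np.int64, copy=True)
        return out

    def write_bedgraph(self, outdir: str | Path) -> None:
        """One run-length-encoded bedGraph file per (sample, strand)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        by_file: dict[tuple[str, str], list[tuple[str, np.ndarray]]] = {}
        for (sample, chrom, strand), arr in sorted(self.data.items()):
            by_file.setdefault((sample, strand), []).append((chrom, arr))
        for (sample, strand), chunks in by_file.items():
            tag = "plus" if strand == "+" else "minus"
            with open(outdir / f"{sample}.{tag}.bedgraph", "w") as fh:
                for chrom, arr in chunks:
                    _write_bedgraph_chrom(fh, chrom, arr, self.bin_size,
                                          self.chrom_lengths[chrom])


def _write_bedgraph_chrom(fh, chrom: str, arr: np.ndarray, bin_size: int,
                          length: int) -> None:
    change = np.flatnonzero(np.diff(arr)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(arr)]))
    for s, e in zip(starts, ends):
        v = arr[s]
        if v == 0:
            continue
        fh.write(f"{chrom}\t{s * bin_size}\t{min(e * bin_size, length)}\t{v}\n")


def read_bedgraph(path: str | Path, chrom_lengths: dict[str, int],
                  bin_size: int) -> dict[str, np.ndarray]:
    """Read a bin-aligned bedGraph back into per-chromosome arrays."""
    out = {c: np.zeros(-(-l // bin_size), dtype=np.int64)
           for c, l in chrom_lengths.items()}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "#")):
                continue
            chrom, s, e, v = line.split()[:4]
            b0, b1 = int(s) // bin_size, -(-int(e) // bin_size)
            out[chrom][b0:b1] = int(float(v))
    return out


def read_tsv_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_tsv_matrix(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t")


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
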