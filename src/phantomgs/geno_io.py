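"""Read, validate, filter and thin inbred genotype panels; profile adjacent-marker LD.

Genotypes are held as minor-allele indicator matrices over fully homozygous
(inbred) accessions: entry ``m[i, k]`` is 1 when accession ``i`` carries the
minor allele at marker ``k``.  Heterozygous or missing calls are rejected on
input — panels of inbred lines should contain neither, and silent imputation
would distort the relationship matrices built downstream.

Two on-disk formats are supported: standard VCF (biallelic SNPs, homozygous
GT fields, read through :mod:`cyvcf2`) and a plain TSV matrix whose header
row carries ``chrom:pos`` marker ids and whose first column is the accession
id.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MarkerMatrix",
    "MarkerPanel",
    "LDProfile",
    "read_genotypes",
    "write_matrix",
    "write_vcf",
    "filter_maf",
    "thin_uniform",
    "adjacent_ld",
    "write_ld_profiles",
    "orient_minor",
]


def _chrom_blocks(chrom: np.ndarray) -> list[tuple[str, int, int]]:
    """Contiguous chromosome runs as (label, start, end) half-open index ranges.

    Raises if a chromosome label recurs after a different one (markers must be
    grouped by chromosome).
    """
    chrom = np.asarray(chrom)
    if chrom.size == 0:
        return []
    change = np.flatnonzero(chrom[1:] != chrom[:-1]) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [chrom.size]))
    labels = [str(chrom[s]) for s in starts]
    if len(set(labels)) != len(labels):
        raise ValueError("chromosome labels must form contiguous blocks")
    return list(zip(labels, starts.tolist(), ends.tolist()))


def orient_minor(values: np.ndarray) -> np.ndarray:
    """Flip indicator columns so that 1 marks the minor allele (frequency <= 0.5)."""
    values = np.asarray(values)
    flip = values.mean(axis=0) > 0.5
    out = values.copy()
    out[:, flip] = 1 - out[:, flip]
    return out


@dataclass
class MarkerMatrix:
    """Accession x marker matrix of minor-allele indicators with coordinates.

    Invariants enforced on construction: all entries in {0, 1}; positions
    strictly increasing within each (contiguous) chromosome block; columns
    minor-allele oriented, so ``maf`` equals the column mean.
    """

    values: np.ndarray
    accession_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    maf: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        self.values = np.ascontiguousarray(np.asarray(self.values, dtype=np.int8))
        self.accession_ids = np.asarray(self.accession_ids)
        self.chrom = np.asarray(self.chrom)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D accession x marker matrix")
        n, p = self.values.shape
        if self.accession_ids.shape != (n,):
            raise ValueError("accession_ids length must match number of rows")
        if self.chrom.shape != (p,) or self.pos.shape != (p,):
            raise ValueError("chrom and pos must have one entry per marker")
        bad = ~np.isin(self.values, (0, 1))
        if bad.any():
            raise ValueError("genotype entries must be 0/1 minor-allele indicators")
        if (self.pos < 0).any():
            raise ValueError("positions must be non-negative")
        for label, s, e in _chrom_blocks(self.chrom):
            if e - s > 1 and not (np.diff(self.pos[s:e]) > 0).all():
                raise ValueError(
                    f"positions must be strictly increasing within chromosome {label}"
                )
        freq = self.values.mean(axis=0)
        if (freq > 0.5 + 1e-12).any():
            k = int(np.argmax(freq))
            raise ValueError(
                f"marker {self.marker_ids()[k]} is not minor-allele oriented "
                f"(indicator frequency {freq[k]:.3f} > 0.5)"
            )
        maf = np.minimum(freq, 1.0 - freq)
        if self.maf is None:
            self.maf = maf
        else:
            self.maf = np.asarray(self.maf, dtype=float)
            if not np.allclose(self.maf, maf, atol=1e-12):
                raise ValueError("supplied maf does not match the genotype matrix")

    @property
    def n_accessions(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    def marker_ids(self) -> list[str]:
        return [f"{c}:{p}" for c, p in zip(self.chrom, self.pos)]

    def subset(self, indices: np.ndarray) -> "MarkerMatrix":
        """New MarkerMatrix restricted to the given (sorted) marker columns."""
        idx = np.asarray(indices, dtype=np.intp)
        return MarkerMatrix(
            values=self.values[:, idx],
            accession_ids=self.accession_ids,
            chrom=self.chrom[idx],
            pos=self.pos[idx],
        )


@dataclass
class MarkerPanel:
    """An ordered subset of a MarkerMatrix's columns at a requested density."""

    source: MarkerMatrix
    indices: np.ndarray
    density_label: int

    def __post_init__(self):
        idx = np.asarray(self.indices, dtype=np.intp)
        if idx.size == 0:
            raise ValueError("panel must contain at least one marker")
        if idx.size != np.unique(idx).size:
            raise ValueError("panel indices must be unique")
        if idx.size > 1 and not (np.diff(idx) > 0).all():
            raise ValueError("panel indices must be sorted")
        if idx.min() < 0 or idx.max() >= self.source.n_markers:
            raise ValueError("panel indices out of range")
        self.indices = idx

    def __len__(self) -> int:
        return int(self.indices.size)

    @property
    def values(self) -> np.ndarray:
        return self.source.values[:, self.indices]

    @property
    def chrom(self) -> np.ndarray:
        return self.source.chrom[self.indices]

    @property
    def pos(self) -> np.ndarray:
        return self.source.pos[self.indices]

    @property
    def maf(self) -> np.ndarray:
        return self.source.maf[self.indices]

    @property
    def accession_ids(self) -> np.ndarray:
        return self.source.accession_ids

    def to_matrix(self) -> MarkerMatrix:
        return self.source.subset(self.indices)


@dataclass
class LDProfile:
    """Pearson r between within-chromosome contiguous marker pairs of a panel."""

    r_values: np.ndarray
    quantiles: dict  # probability -> quantile of |r|
    panel_size: int

    @property
    def n_pairs(self) -> int:
        return int(self.r_values.size)


def read_genotypes(path, format: str = "auto") -> MarkerMatrix:
    """Read a genotype panel from VCF or the delimited matrix format.

    All calls must be homozygous; heterozygous or missing genotypes raise a
    ``ValueError`` naming the offending accession and site.  Columns are
    re-oriented so the indicator marks the minor allele.
    """
    path = str(path)
    if format == "auto":
        format = "vcf" if path.endswith((".vcf", ".vcf.gz")) else "matrix"
    if format == "vcf":
        return _read_vcf(path)
    if format == "matrix":
        return _read_matrix(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_vcf(path: str) -> MarkerMatrix:
    from cyvcf2 import VCF

    v = VCF(path, gts012=True)
    samples = list(v.samples)
    cols, chroms, positions = [], [], []
    for var in v:
        site = f"{var.CHROM}:{var.POS}"
        if len(var.ALT) != 1:
            raise ValueError(f"site {site} is not a biallelic SNP")
        gt = np.asarray(var.gt_types)
        if (gt == 1).any():
            who = samples[int(np.argmax(gt == 1))]
            raise ValueError(f"heterozygous call for accession {who} at site {site}")
        if (gt == 3).any():
            who = samples[int(np.argmax(gt == 3))]
            raise ValueError(f"missing genotype for accession {who} at site {site}")
        cols.append((gt == 2).astype(np.int8))
        chroms.append(var.CHROM)
        positions.append(var.POS)
    if not cols:
        raise ValueError(f"no variant records in {path}")
    values = orient_minor(np.column_stack(cols))
    return MarkerMatrix(values, np.asarray(samples), np.asarray(chroms), np.asarray(positions))


def _read_matrix(path: str) -> MarkerMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    chroms, positions = [], []
    for col in df.columns:
        c, _, p = str(col).rpartition(":")
        if not c or not p.isdigit():
            raise ValueError(f"marker id {col!r} is not of the form chrom:pos")
        chroms.append(c)
        positions.append(int(p))
    if df.isna().any().any():
        acc = df.index[df.isna().any(axis=1)][0]
        raise ValueError(f"missing genotype for accession {acc}")
    values = orient_minor(df.to_numpy())
    return MarkerMatrix(values, df.index.to_numpy(), np.asarray(chroms), np.asarray(positions))


def write_matrix(g: MarkerMatrix, path) -> None:
    """Write the delimited matrix format (round-trips exactly through read_genotypes)."""
    df = pd.DataFrame(g.values, index=pd.Index(g.accession_ids, name="accession"),
                      columns=g.marker_ids())
    df.to_csv(path, sep="\t")


def write_vcf(g: MarkerMatrix, path) -> None:
    """Write a minimal VCF 4.2 file; the indicator allele is written as ALT."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for label, s, e in _chrom_blocks(g.chrom):
            fh.write(f"##contig=<ID={label}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(str(a) for a in g.accession_ids) + "\n")
        for k in range(g.n_markers):
            calls = "\t".join("1/1" if m else "0/0" for m in g.values[:, k])
            fh.write(f"{g.chrom[k]}\t{g.pos[k]}\t.\tA\tT\t.\tPASS\t.\tGT\t{calls}\n")


def filter_maf(g: MarkerMatrix, threshold: float) -> MarkerMatrix:
    """Retain exactly the markers with MAF >= threshold, order preserved."""
    if not 0 <= threshold < 0.5:
        raise ValueError("MAF threshold must be in [0, 0.5)")
    keep = np.flatnonzero(g.maf >= threshold)
    if keep.size == 0:
        raise ValueError(f"no markers with MAF >= {threshold}; panel would be empty")
    if keep.size == g.n_markers:
        return g
    return g.subset(keep)


def _largest_remainder(total: int, weights: np.ndarray) -> np.ndarray:
    """Apportion `total` integer counts proportionally to `weights`."""
    weights = np.asarray(weights, dtype=float)
    quota = total * weights / weights.sum()
    base = np.floor(quota).astype(int)
    short = total - base.sum()
    if short > 0:
        order = np.argsort(-(quota - base), kind="stable")
        base[order[:short]] += 1
    return base


def _nearest_sorted(positions: np.ndarray, queries: np.ndarray) -> np.ndarray:
    """Index of the nearest entry of sorted `positions` for each query; ties -> lower."""
    j = np.searchsorted(positions, queries)
    left = np.clip(j - 1, 0, positions.size - 1)
    right = np.clip(j, 0, positions.size - 1)
    dl = np.abs(queries - positions[left])
    dr = np.abs(positions[right] - queries)
    return np.where(dl <= dr, left, right)


def thin_uniform(g: MarkerMatrix, target_count: int) -> MarkerPanel:
    """Select ~target_count markers uniformly spaced along the physical genome.

    Chromosomes are allotted targets proportionally to their physical span;
    within a chromosome a regular grid of positions is laid down and the
    nearest marker to each grid point is taken (ties towards the lower
    position).  Duplicates are dropped, so the returned panel can be slightly
    smaller than requested.
    """
    if target_count < 1:
        raise ValueError("target_count must be >= 1")
    p = g.n_markers
    if target_count >= p:
        return MarkerPanel(g, np.arange(p), target_count)
    blocks = _chrom_blocks(g.chrom)
    spans = np.array([g.pos[e - 1] - g.pos[s] + 1 for _, s, e in blocks], dtype=float)
    alloc = _largest_remainder(target_count, spans)
    chosen = []
    for (label, s, e), c in zip(blocks, alloc):
        if c == 0:
            continue
        pos_c = g.pos[s:e].astype(float)
        span = pos_c[-1] - pos_c[0] + 1
        grid = pos_c[0] + (np.arange(c) + 0.5) * span / c
        chosen.append(s + _nearest_sorted(pos_c, grid))
    indices = np.unique(np.concatenate(chosen))
    return MarkerPanel(g, indices, target_count)


def adjacent_ld(panel: MarkerPanel) -> LDProfile:
    """Pearson r for every within-chromosome contiguous marker pair of the panel.

    Quantiles at probabilities 0.9 / 0.7 / 0.5 are taken on |r|, so the
    density-LD pattern is free of sign.
    """
    V = panel.values.astype(float)
    sd = V.std(axis=0)
    if (sd == 0).any():
        k = int(np.argmax(sd == 0))
        raise ValueError(
            f"zero-variance marker {panel.chrom[k]}:{panel.pos[k]}; "
            "apply the MAF filter before LD profiling"
        )
    Vc = V - V.mean(axis=0)
    norms = np.sqrt((Vc ** 2).sum(axis=0))
    rs = []
    for _, s, e in _chrom_blocks(panel.chrom):
        if e - s < 2:
            continue
        X = Vc[:, s:e]
        nm = norms[s:e]
        rs.append((X[:, :-1] * X[:, 1:]).sum(axis=0) / (nm[:-1] * nm[1:]))
    if not rs:
        raise ValueError("panel needs >= 2 markers on at least one chromosome")
    r = np.concatenate(rs)
    a = np.abs(r)
    quantiles = {q: float(np.quantile(a, q)) for q in (0.9, 0.7, 0.5)}
    return LDProfile(r_values=r, quantiles=quantiles, panel_size=len(panel))


def write_ld_profiles(profiles: dict, path) -> None:
    """Write LD profiles (panel size -> LDProfile) as TSV (panel_size, q50, q70, q90)."""
    rows = [
        {
            "panel_size": size,
            "q50": prof.quantiles[0.5],
            "q70": prof.quantiles[0.7],
            "q90": prof.quantiles[0.9],
        }
        for size, prof in sorted(profiles.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
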