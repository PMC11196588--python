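"""Genotype panel container, VCF input/output, and panel filtering.

Genotypes are coded per the conventional SNP-array scheme: 0 for the
reference homozygote (0/0), 1 for the heterozygote (0/1 or 1/0), 2 for the
alternate homozygote (1/1) and 9 for a missing ("deletion") call.  Half
calls such as 0/. are coded 9 conservatively.

Three filters operate on a :class:`GenotypePanel`:

* :func:`filter_samples` removes samples whose missing fraction exceeds a
  threshold (default keeps everything except fully missing samples);
* :func:`filter_variants` applies the variant-calling filters — a
  per-genotype depth mask, a per-locus missingness ceiling (inclusive) and
  a minor-allele-frequency floor (inclusive);
* :func:`select_panel_loci` applies the assay-design screen — strict MAF
  and missingness thresholds followed by a greedy left-to-right physical
  spacing rule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    AllLociRemovedError,
    AllSamplesRemovedError,
    MissingGenotypeFormatError,
    MultiallelicSiteError,
    NonDiploidCallError,
)

MISSING = 9
VALID_CODES = frozenset({0, 1, 2, MISSING})

LOCUS_COLUMNS = ["chrom", "pos", "id", "ref", "alt"]


@dataclass
class GenotypePanel:
    """Samples x loci coded-genotype matrix with locus metadata.

    Parameters
    ----------
    sample_ids : list of str
        Ordered, unique sample identifiers.
    loci : pandas.DataFrame
        One row per locus with columns ``chrom, pos, id, ref, alt``;
        positions are 1-based and non-decreasing within a chromosome.
    G : numpy.ndarray
        ``(n_samples, n_loci)`` integer matrix over {0, 1, 2, 9}.
    DP : numpy.ndarray, optional
        Per-genotype sequencing depth, same shape as ``G``.
    """

    sample_ids: list[str]
    loci: pd.DataFrame
    G: np.ndarray
    DP: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sample_ids = list(self.sample_ids)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        self.loci = self.loci.reset_index(drop=True)
        missing_cols = set(LOCUS_COLUMNS) - set(self.loci.columns)
        if missing_cols:
            raise ValueError(f"loci table lacks columns {sorted(missing_cols)}")
        self.G = np.asarray(self.G, dtype=np.int8)
        if self.G.shape != (len(self.sample_ids), len(self.loci)):
            raise ValueError(
                f"G shape {self.G.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.loci)} loci"
            )
        codes = set(np.unique(self.G).tolist())
        if not codes <= VALID_CODES:
            raise ValueError(f"invalid genotype codes {sorted(codes - VALID_CODES)}")
        for _, sub in self.loci.groupby("chrom", sort=False):
            if not sub["pos"].is_monotonic_increasing:
                raise ValueError("positions must be non-decreasing within a chromosome")
        if self.DP is not None:
            self.DP = np.asarray(self.DP)
            if self.DP.shape != self.G.shape:
                raise ValueError("DP shape does not match G")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def locus_ids(self) -> list[str]:
        return self.loci["id"].tolist()

    def called_mask(self) -> np.ndarray:
        return self.G != MISSING

    def sample_missing_rate(self) -> np.ndarray:
        return (self.G == MISSING).mean(axis=1)

    def locus_missing_rate(self) -> np.ndarray:
        return (self.G == MISSING).mean(axis=0)

    def take_samples(self, index: np.ndarray) -> "GenotypePanel":
        index = np.asarray(index)
        return GenotypePanel(
            [self.sample_ids[i] for i in index],
            self.loci.copy(),
            self.G[index],
            None if self.DP is None else self.DP[index],
        )

    def take_loci(self, index: np.ndarray) -> "GenotypePanel":
        index = np.asarray(index)
        return GenotypePanel(
            list(self.sample_ids),
            self.loci.iloc[index],
            self.G[:, index],
            None if self.DP is None else self.DP[:, index],
        )

    def subset_by_sample_ids(self, ids: list[str]) -> "GenotypePanel":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        return self.take_samples(np.array([pos[s] for s in ids], dtype=int))


@dataclass
class FilterReport:
    """Accounting of what a filter removed and why."""

    n_samples_in: int
    n_samples_out: int
    n_loci_in: int
    n_loci_out: int
    removed_samples: list[tuple[str, str]] = field(default_factory=list)
    removed_loci: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_samples_in != self.n_samples_out + len(self.removed_samples):
            raise ValueError("sample counts do not reconcile")
        if self.n_loci_in != self.n_loci_out + len(self.removed_loci):
            raise ValueError("locus counts do not reconcile")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_samples_in": self.n_samples_in,
            "n_samples_out": self.n_samples_out,
            "n_loci_in": self.n_loci_in,
            "n_loci_out": self.n_loci_out,
            "removed_samples": [{"id": i, "reason": r} for i, r in self.removed_samples],
            "removed_loci": [{"id": i, "reason": r} for i, r in self.removed_loci],
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    def to_tsv(self, path: str | Path) -> None:
        rows = [("sample", i, r) for i, r in self.removed_samples]
        rows += [("locus", i, r) for i, r in self.removed_loci]
        pd.DataFrame(rows, columns=["kind", "id", "reason"]).to_csv(
            path, sep="\t", index=False
        )


def read_vcf(path: str | Path) -> GenotypePanel:
    """Read a diploid, biallelic-SNP VCF into a :class:`GenotypePanel`.

    Coding: 0/0 -> 0, 0/1 or 1/0 -> 1, 1/1 -> 2, ./. and half calls -> 9.
    Multi-allelic records and non-diploid calls raise named errors.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows = []
    genos = []
    depths = []
    has_dp = "DP" in [f for f in _format_ids(vcf)]
    for v in vcf:
        if len(v.ALT) != 1:
            raise MultiallelicSiteError(
                f"multi-allelic record at {v.CHROM}:{v.POS} (ALT={','.join(v.ALT)})"
            )
        if v.genotypes is None:
            raise MissingGenotypeFormatError(f"no GT field at {v.CHROM}:{v.POS}")
        row = np.empty(len(samples), dtype=np.int8)
        for i, call in enumerate(v.genotypes):
            alleles = call[:-1]  # last element is the phasing flag
            if len(alleles) != 2:
                raise NonDiploidCallError(
                    f"sample {samples[i]} at {v.CHROM}:{v.POS} has ploidy {len(alleles)}"
                )
            if alleles[0] < 0 or alleles[1] < 0:
                row[i] = MISSING
            else:
                row[i] = alleles[0] + alleles[1]
        genos.append(row)
        if has_dp:
            dp = v.format("DP")
            depths.append(
                np.full(len(samples), -1, dtype=np.int32)
                if dp is None
                else dp.reshape(-1).astype(np.int32)
            )
        vid = v.ID if v.ID not in (None, ".") else f"{v.CHROM}_{v.POS}"
        rows.append((v.CHROM, v.POS, vid, v.REF, v.ALT[0]))
    if not rows:
        raise AllLociRemovedError(f"no records in {path}")
    loci = pd.DataFrame(rows, columns=LOCUS_COLUMNS)
    G = np.vstack(genos).T
    DP = np.vstack(depths).T if has_dp and depths else None
    return GenotypePanel(samples, loci, G, DP)


def _format_ids(vcf) -> list[str]:
    out = []
    for h in vcf.header_iter():
        info = h.info()
        if info.get("HeaderType") == "FORMAT":
            out.append(info.get("ID"))
    return out


def write_vcf(panel: GenotypePanel, path: str | Path) -> None:
    """Write a panel as uncompressed VCF v4.2; inverse of :func:`read_vcf` on ``G``."""
    code_to_gt = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    lines = ["##fileformat=VCFv4.2", "##source=hevecore"]
    for chrom, sub in panel.loci.groupby("chrom", sort=False):
        lines.append(f"##contig=<ID={chrom},length={int(sub['pos'].max()) + 1}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    fmt = "GT"
    if panel.DP is not None:
        lines.append('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
        fmt = "GT:DP"
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(panel.sample_ids)
    )
    for j, locus in panel.loci.iterrows():
        fields = [
            str(locus["chrom"]),
            str(int(locus["pos"])),
            str(locus["id"]),
            str(locus["ref"]),
            str(locus["alt"]),
            ".",
            "PASS",
            ".",
            fmt,
        ]
        for i in range(panel.n_samples):
            gt = code_to_gt[int(panel.G[i, j])]
            if panel.DP is not None:
                gt = f"{gt}:{int(panel.DP[i, j])}"
            fields.append(gt)
        lines.append("\t".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")


def filter_samples(
    panel: GenotypePanel, max_sample_missing: float = 0.999
) -> tuple[GenotypePanel, FilterReport]:
    """Drop samples whose missing fraction exceeds ``max_sample_missing``.

    The default 0.999 removes only fully missing samples, the situation in
    which a sample yields no usable genotype at all and must be excluded.
    """
    if not 0 < max_sample_missing <= 1:
        raise ValueError("max_sample_missing must be in (0, 1]")
    rates = panel.sample_missing_rate()
    keep = rates <= max_sample_missing
    if not keep.any():
        raise AllSamplesRemovedError("sample missingness filter removed every sample")
    removed = [
        (panel.sample_ids[i], f"missing rate {rates[i]:.4f} > {max_sample_missing}")
        for i in np.flatnonzero(~keep)
    ]
    out = panel.take_samples(np.flatnonzero(keep))
    report = FilterReport(
        panel.n_samples, out.n_samples, panel.n_loci, panel.n_loci, removed, []
    )
    return out, report


def _minor_allele_frequency(G: np.ndarray) -> np.ndarray:
    """Per-locus MAF over non-missing alleles; NaN where nothing is called."""
    called = G != MISSING
    n_called = called.sum(axis=0)
    alt = np.where(called, G, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = alt / (2.0 * n_called)
    p = np.where(n_called > 0, p, np.nan)
    return np.minimum(p, 1.0 - p)


def filter_variants(
    panel: GenotypePanel,
    min_depth: int = 20,
    max_locus_missing: float = 0.10,
    min_af: float = 0.05,
) -> tuple[GenotypePanel, FilterReport]:
    """Apply the variant-calling filters.

    Genotypes with depth below ``min_depth`` are first masked to 9 (when a
    DP matrix is available), then loci with a missing fraction above
    ``max_locus_missing`` or a minor-allele frequency below ``min_af`` are
    removed.  Both locus thresholds are inclusive: exactly 10% missing or
    exactly 5% MAF survives.
    """
    if not 0 <= max_locus_missing <= 1 or not 0 <= min_af <= 0.5:
        raise ValueError("thresholds out of range")
    G = panel.G.copy()
    DP = panel.DP
    if min_depth > 0:
        if DP is None:
            raise ValueError("min_depth > 0 requires a DP matrix")
        G[(DP >= 0) & (DP < min_depth)] = MISSING
    masked = GenotypePanel(panel.sample_ids, panel.loci, G, DP)
    miss = masked.locus_missing_rate()
    maf = _minor_allele_frequency(G)
    reasons = {}
    for j in range(masked.n_loci):
        if miss[j] > max_locus_missing:
            reasons[j] = f"missing rate {miss[j]:.4f} > {max_locus_missing}"
        elif np.isnan(maf[j]) or maf[j] < min_af:
            reasons[j] = f"MAF {maf[j]:.4f} < {min_af}"
    keep = np.array([j for j in range(masked.n_loci) if j not in reasons], dtype=int)
    if keep.size == 0:
        raise AllLociRemovedError("variant filter removed every locus")
    removed = [(masked.loci["id"].iat[j], r) for j, r in sorted(reasons.items())]
    out = masked.take_loci(keep)
    report = FilterReport(
        panel.n_samples, out.n_samples, panel.n_loci, out.n_loci, [], removed
    )
    return out, report


def select_panel_loci(
    panel: GenotypePanel,
    min_maf: float = 0.3,
    max_missing: float = 0.5,
    min_spacing_bp: int = 2_000_000,
) -> tuple[GenotypePanel, FilterReport]:
    """Assay-design screen: strict MAF/missingness thresholds plus spacing.

    A locus passes only with MAF strictly above ``min_maf`` and missing
    fraction strictly below ``max_missing`` (strict inequalities, unlike
    :func:`filter_variants`).  Survivors are then thinned greedily left to
    right: a locus is kept only if it lies at least ``min_spacing_bp`` from
    the previously kept locus on the same chromosome.
    """
    miss = panel.locus_missing_rate()
    maf = _minor_allele_frequency(panel.G)
    reasons: dict[int, str] = {}
    last_kept_pos: dict[str, int] = {}
    keep = []
    for j in range(panel.n_loci):
        if np.isnan(maf[j]) or maf[j] <= min_maf:
            reasons[j] = f"MAF {maf[j]:.4f} <= {min_maf}"
            continue
        if miss[j] >= max_missing:
            reasons[j] = f"missing rate {miss[j]:.4f} >= {max_missing}"
            continue
        chrom = panel.loci["chrom"].iat[j]
        pos = int(panel.loci["pos"].iat[j])
        if chrom in last_kept_pos and pos - last_kept_pos[chrom] < min_spacing_bp:
            reasons[j] = (
                f"within {min_spacing_bp} bp of kept locus at "
                f"{chrom}:{last_kept_pos[chrom]}"
            )
            continue
        last_kept_pos[chrom] = pos
        keep.append(j)
    if not keep:
        raise AllLociRemovedError("panel-design screen removed every locus")
    removed = [(panel.loci["id"].iat[j], r) for j, r in sorted(reasons.items())]
    out = panel.take_loci(np.array(keep, dtype=int))
    report = FilterReport(
        panel.n_samples, out.n_samples, panel.n_loci, out.n_loci, [], removed
    )
    return out, report
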