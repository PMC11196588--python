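"""Per-locus and per-population diversity statistics.

Three standard statistics are computed from allele frequencies at each
biallelic SNP:

* expected heterozygosity (gene diversity)  He = 2 p (1 - p);
* polymorphism information content (Botstein's measure)
  PIC = 1 - (p^2 + q^2) - 2 p^2 q^2  with q = 1 - p;
* per-site nucleotide diversity, the average pairwise allelic difference
  among the n called alleles,  pi = n_ref * n_alt / C(n, 2)
  = (n / (n - 1)) * He — the site-pi convention of VCFtools.

He carries no small-sample correction while pi carries the pairwise
n/(n-1) factor, so at p = 0.5 with 195 fully called diploids He is
exactly 0.5 and pi slightly exceeds it (0.5013).  Missing genotypes
(code 9) are excluded from every denominator.  Reported values are
rounded to four decimals only at output; internal computation keeps full
precision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AllMissingColumnError, LowSampleWarning
from .genotype_io import MISSING, GenotypePanel

REPORT_DECIMALS = 4


def allele_counts(genotype_column: np.ndarray) -> tuple[int, int]:
    """Count reference and alternate alleles in one coded genotype column."""
    g = np.asarray(genotype_column)
    called = g != MISSING
    if not called.any():
        raise AllMissingColumnError("all genotypes missing; frequencies undefined")
    g = g[called]
    n_het = int((g == 1).sum())
    n_ref = 2 * int((g == 0).sum()) + n_het
    n_alt = 2 * int((g == 2).sum()) + n_het
    return n_ref, n_alt


def expected_heterozygosity(p: float) -> float:
    """Gene diversity 2p(1-p) for a biallelic locus."""
    if not 0 <= p <= 1:
        raise ValueError("allele frequency outside [0, 1]")
    return 2.0 * p * (1.0 - p)


def pic(p: float) -> float:
    """Botstein polymorphism information content for a biallelic locus."""
    if not 0 <= p <= 1:
        raise ValueError("allele frequency outside [0, 1]")
    q = 1.0 - p
    return 1.0 - (p * p + q * q) - 2.0 * p * p * q * q


def nucleotide_diversity(n_ref: int, n_alt: int) -> float:
    """Average pairwise difference among called alleles at one site."""
    n = n_ref + n_alt
    if n < 2:
        raise ValueError("nucleotide diversity needs at least two called alleles")
    return n_ref * n_alt / (n * (n - 1) / 2.0)


@dataclass
class LocusStats:
    """Diversity statistics at a single locus."""

    locus_id: str
    n_called_alleles: int
    p_alt: float
    maf: float
    he: float
    pic: float
    pi: float
    missing_rate: float


def locus_table(panel: GenotypePanel) -> pd.DataFrame:
    """Per-locus statistics table; all-missing loci get NaN rows with a warning."""
    rows = []
    for j, locus_id in enumerate(panel.locus_ids):
        column = panel.G[:, j]
        miss = float((column == MISSING).mean())
        try:
            n_ref, n_alt = allele_counts(column)
        except AllMissingColumnError:
            warnings.warn(f"locus {locus_id} has no called genotypes", UserWarning,
                          stacklevel=2)
            rows.append((locus_id, 0, np.nan, np.nan, np.nan, np.nan, np.nan, miss))
            continue
        n = n_ref + n_alt
        p = n_alt / n
        pi_val = nucleotide_diversity(n_ref, n_alt) if n >= 2 else np.nan
        rows.append(
            (
                locus_id,
                n,
                p,
                min(p, 1.0 - p),
                expected_heterozygosity(p),
                pic(p),
                pi_val,
                miss,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "locus_id",
            "n_called_alleles",
            "p_alt",
            "maf",
            "he",
            "pic",
            "pi",
            "missing_rate",
        ],
    )


def population_summary(
    panel: GenotypePanel, group_labels: np.ndarray | list, add_mean_row: bool = True
) -> pd.DataFrame:
    """Mean/min/max of He, PIC and pi within each labelled group.

    Frequencies are re-estimated inside each group's submatrix.  The final
    ``Mean`` row is the unweighted arithmetic mean of the group means.
    """
    labels = np.asarray(group_labels)
    if labels.shape[0] != panel.n_samples:
        raise ValueError("one label per sample required")
    rows = []
    for group in pd.unique(labels):
        idx = np.flatnonzero(labels == group)
        if idx.size < 2:
            warnings.warn(
                f"group {group} has fewer than 2 samples; statistics are unstable",
                LowSampleWarning,
                stacklevel=2,
            )
        sub = panel.take_samples(idx)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            table = locus_table(sub)
        rows.append(_summary_row(str(group), table, idx.size))
    out = pd.DataFrame(rows)
    if add_mean_row and len(rows) > 1:
        mean_row = {"population": "Mean", "n_samples": int(labels.shape[0])}
        for col in out.columns:
            if col not in ("population", "n_samples"):
                mean_row[col] = float(out[col].mean())
        out = pd.concat([out, pd.DataFrame([mean_row])], ignore_index=True)
    return out


def _summary_row(name: str, table: pd.DataFrame, n_samples: int) -> dict:
    row = {"population": name, "n_samples": n_samples, "n_loci": len(table)}
    for stat in ("he", "pic", "pi"):
        row[f"mean_{stat}"] = float(table[stat].mean())
        row[f"min_{stat}"] = float(table[stat].min())
        row[f"max_{stat}"] = float(table[stat].max())
    return row


def retention_rate(core: pd.Series | dict, original: pd.Series | dict) -> dict:
    """Core diversity as a percentage of the original, per statistic.

    Both arguments are summary rows keyed ``mean_he``/``mean_pic``/``mean_pi``
    (bare ``he``/``pic``/``pi`` keys are accepted).  A zero original value
    yields None with a warning.
    """
    out = {}
    for stat in ("he", "pic", "pi"):
        c = _lookup(core, stat)
        o = _lookup(original, stat)
        if c is None or o is None:
            raise KeyError(f"statistic {stat} absent from a summary")
        if o == 0:
            warnings.warn(f"original {stat} is zero; retention undefined", UserWarning,
                          stacklevel=2)
            out[stat] = None
        else:
            out[stat] = 100.0 * c / o
    return out


def _lookup(row, stat: str):
    for key in (f"mean_{stat}", stat):
        try:
            value = row[key]
        except (KeyError, IndexError):
            continue
        return float(value)
    return None


def round_report(table: pd.DataFrame) -> pd.DataFrame:
    """Round the floating columns of a statistics table for reporting."""
    out = table.copy()
    for col in out.columns:
        if out[col].dtype.kind == "f":
            out[col] = out[col].round(REPORT_DECIMALS)
    return out
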