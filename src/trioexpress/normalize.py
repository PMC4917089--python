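"""TPM normalization, TMM scaling factors, and the expressed-gene filter.

TPM here means transcripts per million *clean tags*: count / library_total
x 10^6, computed from raw totals. A gene is "expressed" in a library iff its
TPM is strictly greater than 1. One TMM (trimmed mean of M-values) scaling
factor is estimated per library against a reference library; downstream
exact tests consume ``effective_size = library_total * scale_factor`` while
TPM itself stays on the raw scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .tables import CountTable

#: Genes are called expressed above this TPM (strict inequality).
EXPRESSED_TPM = 1.0


@dataclass(frozen=True)
class NormalizedTable:
    """Per-gene TPM with per-library scaling factors and effective sizes."""

    counts: pd.DataFrame
    tpm: pd.DataFrame
    expressed: pd.DataFrame
    library_totals: pd.Series
    scale_factors: pd.Series
    effective_sizes: pd.Series
    reference: str

    @property
    def gene_ids(self) -> list[str]:
        return list(self.tpm.index)

    @property
    def library_ids(self) -> list[str]:
        return list(self.tpm.columns)

    def expressed_union(self) -> set:
        """Genes expressed (>1 TPM) in at least one library."""
        mask = self.expressed.any(axis=1)
        return set(self.tpm.index[mask])


def compute_tpm(table: CountTable) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Return (tpm, expressed) frames; errors on a zero-total library."""
    totals = table.library_totals
    if (totals <= 0).any():
        lib = totals.index[int(np.flatnonzero(totals <= 0)[0])]
        raise ValueError(f"library {lib!r} has total 0; cannot normalize")
    tpm = table.counts / totals * 1e6
    return tpm, tpm > EXPRESSED_TPM


def tmm_factor(test, ref, n_test: float | None = None,
               n_ref: float | None = None, trim_m: float = 0.30,
               trim_a: float = 0.05, min_genes: int = 10) -> float:
    """TMM scaling factor of a test library against a reference.

    M(g) = log2((k_test/N_test)/(k_ref/N_ref)) and
    A(g) = (log2(k_test/N_test) + log2(k_ref/N_ref)) / 2 are computed over
    genes with a nonzero count in both libraries; genes in the top/bottom
    ``trim_m`` rank quantiles of M or ``trim_a`` of A are removed, and the
    factor is 2**(inverse-variance weighted mean of the surviving M) with
    approximate variances 1/k_test - 1/N_test + 1/k_ref - 1/N_ref.
    A library against itself (all M = 0) gives exactly 1.0.
    """
    if not (0 <= trim_m < 0.5 and 0 <= trim_a < 0.5):
        raise ValueError("trim fractions must lie in [0, 0.5)")
    obs = np.asarray(test, dtype=float)
    rf = np.asarray(ref, dtype=float)
    if obs.shape != rf.shape:
        raise ValueError("test and reference must cover the same gene set")
    n_o = float(obs.sum()) if n_test is None else float(n_test)
    n_r = float(rf.sum()) if n_ref is None else float(n_ref)
    if n_o <= 0 or n_r <= 0:
        raise ValueError("library totals must be positive")
    with np.errstate(divide="ignore", invalid="ignore"):
        log_r = np.log2((obs / n_o) / (rf / n_r))
        abs_e = (np.log2(obs / n_o) + np.log2(rf / n_r)) / 2.0
        var = (n_o - obs) / (n_o * obs) + (n_r - rf) / (n_r * rf)
    fin = np.isfinite(log_r) & np.isfinite(abs_e)
    log_r, abs_e, var = log_r[fin], abs_e[fin], var[fin]
    if log_r.size == 0 or np.max(np.abs(log_r)) < 1e-6:
        return 1.0
    n = log_r.size
    lo_m = int(np.floor(n * trim_m)) + 1
    hi_m = n + 1 - lo_m
    lo_a = int(np.floor(n * trim_a)) + 1
    hi_a = n + 1 - lo_a
    rank_m = rankdata(log_r)
    rank_a = rankdata(abs_e)
    keep = ((rank_m >= lo_m) & (rank_m <= hi_m)
            & (rank_a >= lo_a) & (rank_a <= hi_a))
    if int(keep.sum()) < min_genes:
        raise ValueError(
            f"only {int(keep.sum())} genes survive TMM trimming (< "
            f"{min_genes}); disable scaling (scaling=False) for this data")
    f = np.sum(log_r[keep] / var[keep]) / np.sum(1.0 / var[keep])
    return float(2.0 ** f)


def effective_sizes(table: CountTable, reference: str, trim_m: float = 0.30,
                    trim_a: float = 0.05, scaling: bool = True
                    ) -> tuple[pd.Series, pd.Series]:
    """Per-library TMM factors against ``reference`` and effective sizes.

    The reference's own factor is exactly 1. With ``scaling=False`` every
    factor is 1 and effective sizes equal raw totals (documented bypass).
    """
    if reference not in table.counts.columns:
        raise ValueError(f"reference library {reference!r} not in table")
    totals = table.library_totals.astype(float)
    factors = {}
    ref_counts = table.counts[reference].to_numpy()
    for lib in table.counts.columns:
        if not scaling or lib == reference:
            factors[lib] = 1.0
        else:
            factors[lib] = tmm_factor(
                table.counts[lib].to_numpy(), ref_counts,
                n_test=totals[lib], n_ref=totals[reference],
                trim_m=trim_m, trim_a=trim_a)
    factors = pd.Series(factors, name="scale_factor")[table.counts.columns]
    eff = (totals * factors).rename("effective_size")
    return factors, eff


def normalize(table: CountTable, reference: str, trim_m: float = 0.30,
              trim_a: float = 0.05, scaling: bool = True) -> NormalizedTable:
    """Full normalization: TPM + expressed mask + TMM effective sizes."""
    tpm, expressed = compute_tpm(table)
    factors, eff = effective_sizes(table, reference, trim_m=trim_m,
                                   trim_a=trim_a, scaling=scaling)
    return NormalizedTable(counts=table.counts, tpm=tpm, expressed=expressed,
                           library_totals=table.library_totals,
                           scale_factors=factors, effective_sizes=eff,
                           reference=reference)
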