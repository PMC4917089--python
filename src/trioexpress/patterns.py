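"""Trio DEG calling and heterosis expression-pattern classification.

The trio is (AC, BC, CC): two F1 hybrids sharing the paternal inbred CC.
A trio DEG is a gene significantly and concordantly ordered across the trio
(AC>BC>CC or AC<BC<CC); both hybrid-vs-CC tests must be significant in the
same direction and the AC/BC ranking is decided by TPM (optionally, strict
mode also requires the AC-vs-BC test to be significant).

Each trio DEG is then classified per hybrid against its own parents:

* additive          — not significantly different from the mid-parent value;
* over-dominance    — significantly above both parents ("above high-parent");
* under-dominance   — significantly below both parents ("below low-parent");
* maternal-ELD      — expression-level dominance of the maternal parent:
                      indistinguishable from the maternal line yet different
                      from the paternal line;
* paternal-ELD      — the symmetric case;
* other-nonadditive — non-additive but none of the above.

The mid-parent null takes the hybrid count as Binomial(n_h, p0) with
p0 = (p_maternal + p_paternal) / 2, equal parental weights, a plug-in null
that ignores parental sampling noise. Parental proportions and the hybrid
size are on the TMM-effective scale so the test shares the calibration of
the pairwise tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import exact_ratio, percent
from .detest import bh_adjust, exact_binomial_p
from .normalize import NormalizedTable

CATEGORIES = ("additive", "over-dominance", "under-dominance",
              "maternal-ELD", "paternal-ELD", "other-nonadditive")

NONADDITIVE = CATEGORIES[1:]


@dataclass(frozen=True)
class TrioDEGSet:
    """Genes in the two monotone trio classes."""

    up: frozenset  # AC > BC > CC
    down: frozenset  # AC < BC < CC

    def __post_init__(self):
        if self.up & self.down:
            raise ValueError("up and down trio sets must be disjoint")

    @property
    def total(self) -> int:
        return len(self.up) + len(self.down)

    def genes(self) -> frozenset:
        return self.up | self.down


def call_trio_degs(de_ac_cc: pd.DataFrame, de_bc_cc: pd.DataFrame,
                   de_ac_bc: pd.DataFrame, norm: NormalizedTable,
                   strict_trio: bool = False) -> TrioDEGSet:
    """Call trio DEGs from the three pairwise comparisons.

    Membership: both hybrid-vs-CC calls significant and concordant, hybrids
    ranked by TPM (``strict_trio`` additionally requires a significant
    AC-vs-BC call in the matching direction). Genes whose two hybrid-vs-CC
    calls disagree in direction are excluded from both sets.
    """
    ac = de_ac_cc.attrs.get("lib_a")
    cc = de_ac_cc.attrs.get("lib_b")
    bc = de_bc_cc.attrs.get("lib_a")
    if de_bc_cc.attrs.get("lib_b") != cc:
        raise ValueError("the two hybrid comparisons must share the paternal "
                         "reference library")
    if (de_ac_bc.attrs.get("lib_a"), de_ac_bc.attrs.get("lib_b")) != (ac, bc):
        raise ValueError("third comparison must be hybrid A vs hybrid B")
    universe = set(norm.tpm.index)
    for de in (de_ac_cc, de_bc_cc, de_ac_bc):
        if not set(de.index) <= universe:
            raise ValueError("DE calls refer to genes outside the normalized "
                             "table; comparisons must share one table")

    def _sig(de: pd.DataFrame, direction: str) -> set:
        hit = de["significant"] & (de["direction"] == direction)
        return set(de.index[hit])

    tpm_ac = norm.tpm[ac]
    tpm_bc = norm.tpm[bc]
    up = {g for g in _sig(de_ac_cc, "up") & _sig(de_bc_cc, "up")
          if tpm_ac[g] > tpm_bc[g]}
    down = {g for g in _sig(de_ac_cc, "down") & _sig(de_bc_cc, "down")
            if tpm_ac[g] < tpm_bc[g]}
    if strict_trio:
        up &= _sig(de_ac_bc, "up")
        down &= _sig(de_ac_bc, "down")
    return TrioDEGSet(up=frozenset(up), down=frozenset(down))


def midparent_test(k_h: int, n_h: float, tpm_m: float, tpm_p: float
                   ) -> tuple[float, str]:
    """Exact test of a hybrid count against the mid-parent expectation.

    Under additivity the hybrid proportion is p0 = (tpm_m + tpm_p) / 2 / 1e6
    (parental proportions in per-million units, equal weights); the hybrid
    count is Binomial(round(n_h), p0), two-sided by minimum likelihood.
    p0 = 0 with a nonzero hybrid count means expression impossible under the
    null: p = 0, direction 'up' (hybrid-only expression), not an error.
    """
    if tpm_m < 0 or tpm_p < 0:
        raise ValueError("parental TPM must be non-negative")
    if k_h < 0:
        raise ValueError("hybrid count must be non-negative")
    if tpm_m + tpm_p <= 0 and k_h == 0:
        raise ValueError("no expression in parents or hybrid; gene should be "
                         "skipped")
    n = int(round(n_h))
    if n < 1:
        raise ValueError("hybrid effective size must round to >= 1")
    p0 = min(0.5 * (tpm_m + tpm_p) / 1e6, 1.0)
    if p0 <= 0.0:
        return 0.0, "up"
    p_raw = exact_binomial_p(min(k_h, n), n, p0)
    frac = k_h / n
    if frac > p0:
        direction = "up"
    elif frac < p0:
        direction = "down"
    else:
        direction = "none"
    return p_raw, direction


def classify_gene(mid_significant: bool, vs_maternal_sig: bool,
                  vs_maternal_dir: str, vs_paternal_sig: bool,
                  vs_paternal_dir: str) -> str:
    """Decision tree over the three calls for one gene in one hybrid.

    Branch order: additive, over-dominance, under-dominance, maternal-ELD,
    paternal-ELD, other-nonadditive (mutually exclusive, exhaustive).
    """
    if not mid_significant:
        return "additive"
    if (vs_maternal_sig and vs_maternal_dir == "up"
            and vs_paternal_sig and vs_paternal_dir == "up"):
        return "over-dominance"
    if (vs_maternal_sig and vs_maternal_dir == "down"
            and vs_paternal_sig and vs_paternal_dir == "down"):
        return "under-dominance"
    if not vs_maternal_sig and vs_paternal_sig:
        return "maternal-ELD"
    if not vs_paternal_sig and vs_maternal_sig:
        return "paternal-ELD"
    return "other-nonadditive"


def classify_hybrid(trio: TrioDEGSet, norm: NormalizedTable, hybrid: str,
                    maternal: str, paternal: str, alpha: float = 0.05,
                    de_vs_maternal: pd.DataFrame | None = None,
                    de_vs_paternal: pd.DataFrame | None = None
                    ) -> pd.DataFrame:
    """Classify every trio DEG for one hybrid.

    Hybrid-vs-parent calls reuse :func:`~trioexpress.detest.pairwise_de`
    (their BH families are those comparisons'); a trio gene absent from a
    parent comparison's family counts as not significant there. Mid-parent
    p-values are BH-adjusted over this hybrid's trio DEG family.
    """
    if maternal == paternal:
        raise ValueError("maternal and paternal libraries must differ")
    from .detest import pairwise_de  # deferred to avoid cycle at import time
    if de_vs_maternal is None:
        de_vs_maternal = pairwise_de(norm, hybrid, maternal, alpha)
    if de_vs_paternal is None:
        de_vs_paternal = pairwise_de(norm, hybrid, paternal, alpha)

    order = [g for g in norm.tpm.index if g in trio.up or g in trio.down]
    cols = {c: [] for c in
            ("gene_id", "hybrid", "direction", "sig_vs_maternal",
             "dir_vs_maternal", "p_adj_vs_maternal", "sig_vs_paternal",
             "dir_vs_paternal", "p_adj_vs_paternal", "p_mid_raw", "dir_mid")}
    n_h = float(norm.effective_sizes[hybrid])

    def _parent_call(de: pd.DataFrame, g: str) -> tuple[bool, str, float]:
        if g in de.index:
            row = de.loc[g]
            return bool(row["significant"]), str(row["direction"]), \
                float(row["p_adj"])
        return False, "none", float("nan")

    for g in order:
        k_h = int(norm.counts.loc[g, hybrid])
        tpm_m_eff = float(norm.counts.loc[g, maternal]
                          / norm.effective_sizes[maternal] * 1e6)
        tpm_p_eff = float(norm.counts.loc[g, paternal]
                          / norm.effective_sizes[paternal] * 1e6)
        p_mid, dir_mid = midparent_test(k_h, n_h, tpm_m_eff, tpm_p_eff)
        m_sig, m_dir, m_padj = _parent_call(de_vs_maternal, g)
        p_sig, p_dir, p_padj = _parent_call(de_vs_paternal, g)
        cols["gene_id"].append(g)
        cols["hybrid"].append(hybrid)
        cols["direction"].append("up" if g in trio.up else "down")
        cols["sig_vs_maternal"].append(m_sig)
        cols["dir_vs_maternal"].append(m_dir)
        cols["p_adj_vs_maternal"].append(m_padj)
        cols["sig_vs_paternal"].append(p_sig)
        cols["dir_vs_paternal"].append(p_dir)
        cols["p_adj_vs_paternal"].append(p_padj)
        cols["p_mid_raw"].append(p_mid)
        cols["dir_mid"].append(dir_mid)

    records = pd.DataFrame(cols).set_index("gene_id")
    if len(records):
        records["p_mid_adj"] = bh_adjust(records["p_mid_raw"].to_numpy())
    else:
        records["p_mid_adj"] = []
    records["sig_mid"] = records["p_mid_adj"] < alpha
    records["category"] = [
        classify_gene(bool(r.sig_mid), bool(r.sig_vs_maternal),
                      r.dir_vs_maternal, bool(r.sig_vs_paternal),
                      r.dir_vs_paternal)
        for r in records.itertuples()
    ] if len(records) else []
    records.attrs.update(hybrid=hybrid, maternal=maternal, paternal=paternal,
                         alpha=alpha)
    return records


def intersect_patterns(records_a: pd.DataFrame, records_b: pd.DataFrame,
                       category: str, direction: str | None = None
                       ) -> frozenset:
    """Genes carrying ``category`` in both hybrids (optionally one direction).

    Symmetric and idempotent; maternal-ELD intersections are reported
    per direction (activated vs repressed) by passing ``direction``.
    """
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}")

    def _set(rec: pd.DataFrame) -> set:
        if not len(rec):
            return set()
        hit = rec["category"] == category
        if direction is not None:
            hit &= rec["direction"] == direction
        return set(rec.index[hit])

    return frozenset(_set(records_a) & _set(records_b))


@dataclass(frozen=True)
class PatternSummary:
    """Counts and exactly-rounded percentages of the pattern partition.

    ``counts`` maps (hybrid, direction, category) -> gene count, where
    direction is 'up' or 'down'. All percentages are re-derived from counts
    at render time with half-up two-decimal rounding: non-additive shares are
    over the trio DEG total, per-category shares over that direction's
    non-additive count, and the maternal-ELD fold ratio is the larger hybrid
    total over the smaller.
    """

    hybrids: tuple[str, str]
    counts: dict
    intersections: dict = field(default_factory=dict)

    @classmethod
    def from_counts(cls, hybrids, counts: dict, intersections: dict | None
                    = None) -> "PatternSummary":
        for (h, d, c), v in counts.items():
            if c not in CATEGORIES:
                raise ValueError(f"unknown category {c!r}")
            if d not in ("up", "down"):
                raise ValueError(f"unknown direction {d!r}")
            if v < 0:
                raise ValueError("counts must be non-negative")
        return cls(hybrids=tuple(hybrids), counts=dict(counts),
                   intersections=dict(intersections or {}))

    def count(self, hybrid: str, direction: str, category: str) -> int:
        return int(self.counts.get((hybrid, direction, category), 0))

    def direction_total(self, hybrid: str, direction: str) -> int:
        return sum(self.count(hybrid, direction, c) for c in CATEGORIES)

    def trio_total(self, hybrid: str | None = None) -> int:
        h = hybrid or self.hybrids[0]
        return self.direction_total(h, "up") + self.direction_total(h, "down")

    def additive_total(self, hybrid: str) -> int:
        return (self.count(hybrid, "up", "additive")
                + self.count(hybrid, "down", "additive"))

    def nonadditive_total(self, hybrid: str, direction: str | None = None
                          ) -> int:
        dirs = (direction,) if direction else ("up", "down")
        return sum(self.count(hybrid, d, c) for d in dirs
                   for c in NONADDITIVE)

    def maternal_eld_total(self, hybrid: str) -> int:
        return (self.count(hybrid, "up", "maternal-ELD")
                + self.count(hybrid, "down", "maternal-ELD"))

    # -- derived ratios (always recomputed, half-up 2-decimal rounding) -----

    def pct_direction(self, direction: str) -> float | None:
        h = self.hybrids[0]
        return percent(self.direction_total(h, direction), self.trio_total(h))

    def pct_nonadditive(self, hybrid: str) -> float | None:
        return percent(self.nonadditive_total(hybrid), self.trio_total(hybrid))

    def pct_additive(self, hybrid: str) -> float | None:
        return percent(self.additive_total(hybrid), self.trio_total(hybrid))

    def pct_category(self, hybrid: str, direction: str, category: str
                     ) -> float | None:
        return percent(self.count(hybrid, direction, category),
                       self.nonadditive_total(hybrid, direction))

    def maternal_eld_fold_ratio(self) -> float | None:
        a = self.maternal_eld_total(self.hybrids[0])
        b = self.maternal_eld_total(self.hybrids[1])
        return exact_ratio(max(a, b), min(a, b)) if min(a, b) else None


def summarize_patterns(records_a: pd.DataFrame, records_b: pd.DataFrame
                       ) -> PatternSummary:
    """Tabulate both hybrids' pattern records into a :class:`PatternSummary`.

    Also computes the cross-hybrid intersections (over-dominance,
    under-dominance, maternal-ELD split by direction) and checks the
    partition invariant additive + non-additive = trio total per hybrid.
    """
    hybrids = []
    counts: dict = {}
    for rec in (records_a, records_b):
        h = rec.attrs.get("hybrid", "?")
        hybrids.append(h)
        for d in ("up", "down"):
            for c in CATEGORIES:
                n = int(((rec["direction"] == d)
                         & (rec["category"] == c)).sum()) if len(rec) else 0
                counts[(h, d, c)] = n
    inter = {
        "over-dominance": len(intersect_patterns(records_a, records_b,
                                                 "over-dominance")),
        "under-dominance": len(intersect_patterns(records_a, records_b,
                                                  "under-dominance")),
        "maternal-ELD-up": len(intersect_patterns(records_a, records_b,
                                                  "maternal-ELD", "up")),
        "maternal-ELD-down": len(intersect_patterns(records_a, records_b,
                                                    "maternal-ELD", "down")),
    }
    summary = PatternSummary.from_counts(hybrids, counts, inter)
    for h in hybrids:
        assert (summary.additive_total(h) + summary.nonadditive_total(h)
                == summary.trio_total(h))
    return summary


def format_summary(summary: PatternSummary) -> pd.DataFrame:
    """Render the summary as rows (metric, hybrid, direction, category,
    count, denominator, value) with percentages/ratios re-derived from the
    counts. Undefined ratios (zero denominator) are ``None``, never 0."""
    rows = []
    h0 = summary.hybrids[0]
    trio = summary.trio_total()
    for d in ("up", "down"):
        rows.append(("trio_direction_share", "", d, "",
                     summary.direction_total(h0, d), trio,
                     summary.pct_direction(d)))
    for h in summary.hybrids:
        rows.append(("additive_share", h, "", "additive",
                     summary.additive_total(h), summary.trio_total(h),
                     summary.pct_additive(h)))
        rows.append(("nonadditive_share", h, "", "non-additive",
                     summary.nonadditive_total(h), summary.trio_total(h),
                     summary.pct_nonadditive(h)))
        for d in ("up", "down"):
            denom = summary.nonadditive_total(h, d)
            for c in NONADDITIVE:
                rows.append(("category_share", h, d, c,
                             summary.count(h, d, c), denom,
                             summary.pct_category(h, d, c)))
    a = summary.maternal_eld_total(summary.hybrids[0])
    b = summary.maternal_eld_total(summary.hybrids[1])
    rows.append(("maternal_eld_fold_ratio", "", "", "maternal-ELD",
                 max(a, b), min(a, b), summary.maternal_eld_fold_ratio()))
    for name, n in summary.intersections.items():
        rows.append(("common_genes", "", "", name, n, None, None))
    return pd.DataFrame(rows, columns=["metric", "hybrid", "direction",
                                       "category", "count", "denominator",
                                       "value"])
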