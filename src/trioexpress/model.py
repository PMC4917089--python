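"""statsmodels-style front end: a model bound to the five-library design,
whose ``fit()`` runs normalization, pairwise exact tests, trio DEG calling
and pattern classification, returning a results object that carries every
intermediate table, renders a summary, and writes the full output manifest.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from ._util import PipelineError
from .enrich import FDR_THRESHOLD, P_THRESHOLD, enrich
from .normalize import NormalizedTable, normalize
from .patterns import (PatternSummary, TrioDEGSet, call_trio_degs,
                       classify_hybrid, format_summary, summarize_patterns)
from .tables import ROLES, AnnotationTable, CountTable, read_count_table


def _check_roles(roles: dict, libraries) -> dict:
    for role in ROLES:
        if role not in roles:
            raise PipelineError(f"role mapping is missing role {role!r}")
    ids = [roles[r] for r in ROLES]
    if len(set(ids)) != len(ids):
        raise PipelineError("role mapping must be a bijection onto five "
                            "distinct library ids")
    for role, lib in roles.items():
        if lib not in list(libraries):
            raise PipelineError(
                f"library {lib!r} (role {role}) not in count table")
    return {r: roles[r] for r in ROLES}


class TrioExpressionModel:
    """Two-hybrid / three-parent expression-pattern model.

    Parameters
    ----------
    counts : CountTable
        Raw tag counts for the five libraries.
    roles : dict
        Mapping of the roles AA, BB, CC, AC, BC to library ids, e.g.
        ``{"AA": "Zheng58", "BB": "Ye478", "CC": "Chang7-2",
        "AC": "Zhengdan958", "BC": "Anyu5"}``.
    alpha : float
        BH-adjusted significance threshold for every test (default 0.05).
    reference_role : str
        Role anchoring the TMM factors (default the shared paternal CC).
    trim_m, trim_a : float
        TMM trim fractions for M values and A values.
    scaling : bool
        Disable to force all scale factors to 1.
    strict_trio : bool
        Require the hybrid-vs-hybrid test to be significant for trio
        membership (default off: the hybrid ranking is decided by TPM).
    """

    def __init__(self, counts: CountTable, roles: dict, alpha: float = 0.05,
                 reference_role: str = "CC", trim_m: float = 0.30,
                 trim_a: float = 0.05, scaling: bool = True,
                 strict_trio: bool = False):
        self.counts = counts
        self.roles = _check_roles(roles, counts.library_ids)
        if reference_role not in ROLES:
            raise PipelineError(f"unknown reference role {reference_role!r}")
        self.alpha = alpha
        self.reference_role = reference_role
        self.trim_m = trim_m
        self.trim_a = trim_a
        self.scaling = scaling
        self.strict_trio = strict_trio

    @classmethod
    def from_tsv(cls, path, roles: dict, **kwargs) -> "TrioExpressionModel":
        return cls(read_count_table(path), roles, **kwargs)

    def fit(self) -> "TrioExpressionResults":
        from .detest import pairwise_de
        r = self.roles
        try:
            norm = normalize(self.counts, reference=r[self.reference_role],
                             trim_m=self.trim_m, trim_a=self.trim_a,
                             scaling=self.scaling)
        except ValueError as exc:
            raise PipelineError(f"normalize: {exc}") from exc
        pairs = [("AC", "CC"), ("BC", "CC"), ("AC", "BC"), ("AC", "AA"),
                 ("BC", "BB")]
        de = {}
        for a, b in pairs:
            try:
                de[f"{a}_vs_{b}"] = pairwise_de(norm, r[a], r[b], self.alpha)
            except ValueError as exc:
                raise PipelineError(f"de_test {a} vs {b}: {exc}") from exc
        try:
            trio = call_trio_degs(de["AC_vs_CC"], de["BC_vs_CC"],
                                  de["AC_vs_BC"], norm,
                                  strict_trio=self.strict_trio)
            rec_ac = classify_hybrid(trio, norm, r["AC"], r["AA"], r["CC"],
                                     self.alpha,
                                     de_vs_maternal=de["AC_vs_AA"],
                                     de_vs_paternal=de["AC_vs_CC"])
            rec_bc = classify_hybrid(trio, norm, r["BC"], r["BB"], r["CC"],
                                     self.alpha,
                                     de_vs_maternal=de["BC_vs_BB"],
                                     de_vs_paternal=de["BC_vs_CC"])
            summary = summarize_patterns(rec_ac, rec_bc)
        except ValueError as exc:
            raise PipelineError(f"trio_patterns: {exc}") from exc
        return TrioExpressionResults(model=self, normalized=norm, de_calls=de,
                                     trio=trio,
                                     patterns={"AC": rec_ac, "BC": rec_bc},
                                     pattern_summary=summary)


@dataclass
class TrioExpressionResults:
    """Fitted trio-expression analysis.

    Attributes
    ----------
    normalized : NormalizedTable
    de_calls : dict of DataFrame
        Pairwise calls keyed 'AC_vs_CC', 'BC_vs_CC', 'AC_vs_BC',
        'AC_vs_AA', 'BC_vs_BB' (role names; columns use library ids).
    trio : TrioDEGSet
    patterns : dict of DataFrame
        Per-hybrid classification records keyed 'AC', 'BC'.
    pattern_summary : PatternSummary
    """

    model: TrioExpressionModel
    normalized: NormalizedTable
    de_calls: dict
    trio: TrioDEGSet
    patterns: dict
    pattern_summary: PatternSummary

    def summary(self) -> str:
        """Plain-text account of the fit (counts re-derived at render time)."""
        r = self.model.roles
        lines = ["Trio expression-pattern analysis",
                 "=" * 48]
        lines.append("libraries (role = id, total tags, TMM factor):")
        for role in ROLES:
            lib = r[role]
            lines.append(
                f"  {role} = {lib:<14s} {int(self.normalized.library_totals[lib]):>10d}"
                f"  x{self.normalized.scale_factors[lib]:.4f}")
        lines.append(f"alpha = {self.model.alpha}; reference = "
                     f"{self.model.reference_role}; strict_trio = "
                     f"{self.model.strict_trio}")
        lines.append(f"trio DEGs: {self.trio.total} "
                     f"(up {len(self.trio.up)}, down {len(self.trio.down)})")
        lines.append("")
        table = format_summary(self.pattern_summary)
        with pd.option_context("display.max_rows", None,
                               "display.width", 120):
            lines.append(table.to_string(index=False, na_rep="undefined"))
        return "\n".join(lines)

    def enrich(self, annotations: AnnotationTable, genes=None,
               category: str | None = None, hybrid: str = "AC",
               direction: str | None = None,
               p_threshold: float = P_THRESHOLD,
               fdr_threshold: float = FDR_THRESHOLD) -> pd.DataFrame:
        """GO enrichment of a gene set (explicit, or a pattern category of
        one hybrid) against the expressed-gene background."""
        if genes is None:
            if category is None:
                raise ValueError("pass either genes or category")
            rec = self.patterns[hybrid]
            hit = rec["category"] == category
            if direction is not None:
                hit &= rec["direction"] == direction
            genes = set(rec.index[hit])
        background = self.normalized.expressed_union()
        return enrich(genes, annotations, background,
                      p_threshold=p_threshold, fdr_threshold=fdr_threshold)

    def save(self, outdir) -> dict:
        """Write every intermediate and final table plus a run log; returns
        the manifest (name -> path), also written as manifest.json."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        manifest = {}

        def _write(name, fn):
            path = out / name
            fn(path)
            manifest[name] = str(path)

        norm = self.normalized
        norm_table = norm.tpm.add_suffix("_tpm").join(
            norm.expressed.add_suffix("_expressed"))
        _write("normalized.tsv",
               lambda p: norm_table.to_csv(p, sep="\t"))
        factors = pd.DataFrame({"library_total": norm.library_totals,
                                "scale_factor": norm.scale_factors,
                                "effective_size": norm.effective_sizes})
        _write("scale_factors.tsv", lambda p: factors.to_csv(p, sep="\t"))
        for key, de in self.de_calls.items():
            _write(f"de_{key}.tsv", lambda p, de=de: de.to_csv(p, sep="\t"))
        _write("trio_up_genes.txt", lambda p: p.write_text(
            "".join(f"{g}\n" for g in sorted(self.trio.up))))
        _write("trio_down_genes.txt", lambda p: p.write_text(
            "".join(f"{g}\n" for g in sorted(self.trio.down))))
        for h, rec in self.patterns.items():
            _write(f"patterns_{h}.tsv",
                   lambda p, rec=rec: rec.to_csv(p, sep="\t"))
        _write("pattern_summary.tsv",
               lambda p: format_summary(self.pattern_summary).to_csv(
                   p, sep="\t", index=False, na_rep="undefined"))
        inter = pd.DataFrame(
            sorted(self.pattern_summary.intersections.items()),
            columns=["category", "common_genes"])
        _write("intersections.tsv",
               lambda p: inter.to_csv(p, sep="\t", index=False))

        log = [f"trioexpress {__version__}",
               f"run at {datetime.datetime.now().isoformat()}",
               f"roles: {self.model.roles}",
               f"alpha: {self.model.alpha}",
               f"reference_role: {self.model.reference_role}",
               f"trim_m: {self.model.trim_m}  trim_a: {self.model.trim_a}",
               f"scaling: {self.model.scaling}  strict_trio: "
               f"{self.model.strict_trio}",
               "library totals: "
               + ", ".join(f"{k}={int(v)}"
                           for k, v in norm.library_totals.items()),
               "outputs: " + ", ".join(sorted(manifest))]
        (out / "run_log.txt").write_text("\n".join(log) + "\n")
        manifest["run_log.txt"] = str(out / "run_log.txt")
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      sort_keys=True) + "\n")
        return manifest


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end run configuration (YAML-loadable)."""

    counts_path: str
    roles: dict
    output_dir: str
    annotations_path: str | None = None
    annotations_dialect: str = "tsv"
    alpha: float = 0.05
    p_threshold: float = P_THRESHOLD
    fdr_threshold: float = FDR_THRESHOLD
    trim_m: float = 0.30
    trim_a: float = 0.05
    reference_role: str = "CC"
    scaling: bool = True
    strict_trio: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the whole analysis from a config; returns the output manifest."""
    from .tables import read_annotations
    model = TrioExpressionModel.from_tsv(
        config.counts_path, config.roles, alpha=config.alpha,
        reference_role=config.reference_role, trim_m=config.trim_m,
        trim_a=config.trim_a, scaling=config.scaling,
        strict_trio=config.strict_trio)
    results = model.fit()
    manifest = results.save(config.output_dir)
    if config.annotations_path:
        annotations = read_annotations(config.annotations_path,
                                       dialect=config.annotations_dialect)
        out = Path(config.output_dir)
        for category in ("over-dominance", "under-dominance", "maternal-ELD"):
            for hybrid in ("AC", "BC"):
                rec = results.patterns[hybrid]
                genes = set(rec.index[rec["category"] == category])
                if not genes:
                    continue
                table = results.enrich(annotations, genes=genes,
                                       p_threshold=config.p_threshold,
                                       fdr_threshold=config.fdr_threshold)
                name = f"enrich_{hybrid}_{category}.tsv"
                table.to_csv(out / name, sep="\t", index=False)
                manifest[name] = str(out / name)
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
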