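"""Synthetic five-library tag-count experiments with planted ground truth.

The generator emulates the statistical structure of an unreplicated
two-hybrid digital-gene-expression design: five pooled libraries (maternal
inbreds AA and BB, shared paternal inbred CC, hybrids AC and BC), on the
order of 10^6 tags each, with Poisson (optionally negative-binomial) count
noise and per-gene expression-pattern classes planted as ground truth.

Pattern geometry (s = effect_size, rho = hybrid_separation, b = planted
baseline TPM). The BC-side levels are separated from the AC side by rho so
the trio ordering AC>BC>CC / AC<BC<CC is deterministic in expectation:

==============  =======  ==========  =======  ==============  =============
class           AA       BB          CC       AC              BC
==============  =======  ==========  =======  ==============  =============
over-dominance  b        rho*b       rho^2*b  s*b             s*rho*b
under-dominance rho*b    b           b/rho    rho*b/s         b/s
maternal-ELD up s*b      s*rho*b     b        s*b             s*rho*b
maternal-ELD dn b/s      b/(s*rho)   b        b/s             b/(s*rho)
paternal-ELD    s*b      s*rho*b     b        b               b
additive up     s*b      s*rho*b     b        mid(AA,CC)      mid(BB,CC)
additive dn     b/s^2    b/3         b        mid(AA,CC)      mid(BB,CC)
==============  =======  ==========  =======  ==============  =============

Hybrids of over-/under-dominance genes sit exactly at
max(parents)*s / min(parents)/s; ELD hybrids equal their maternal parent
exactly; additive hybrids sit exactly at the mid-parent value. Background
genes are null: both hybrids at the exact mid-parent of their own parents,
with a configurable fraction of genes where the two maternal lines diverge
(echoing the observed ~18% maternal transcriptome difference).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .tables import AnnotationTable, CountTable

PATTERN_CLASSES = ("over-dominance", "under-dominance", "maternal-ELD",
                   "paternal-ELD", "additive", "none")

_LIBS = ("AA", "BB", "CC", "AC", "BC")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of a synthetic experiment.

    Defaults are the scale the recovery analyses run at: 2,000 genes,
    10^6-tag libraries, 4-fold pattern effects, Poisson noise. Planted
    pattern genes are placed at well-expressed baselines (300-900 TPM) so
    label recovery measures the classifier rather than sequencing depth.
    """

    n_genes: int = 2000
    depth: int = 1_000_000
    frac_over: float = 0.025
    frac_under: float = 0.025
    frac_maternal_eld: float = 0.025
    frac_paternal_eld: float = 0.0
    frac_additive: float = 0.12
    effect_size: float = 4.0
    baseline_sdlog: float = 0.5
    planted_tpm_range: tuple = (300.0, 900.0)
    shared_maternal_fraction: float = 0.82
    maternal_sdlog2: float = 1.0
    hybrid_separation: float = 0.7
    noise: str = "poisson"
    dispersion: float = 0.0
    seed: int = 0

    def __post_init__(self):
        fracs = (self.frac_over, self.frac_under, self.frac_maternal_eld,
                 self.frac_paternal_eld, self.frac_additive)
        if any(f < 0 for f in fracs):
            raise ValueError("pattern fractions must be non-negative")
        if sum(fracs) > 1:
            raise ValueError("pattern fractions must sum to <= 1")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.effect_size <= 1:
            raise ValueError("effect_size must exceed 1")
        if self.noise not in ("poisson", "negative_binomial"):
            raise ValueError(f"unknown noise model {self.noise!r}")
        if self.noise == "negative_binomial" and self.dispersion <= 0:
            raise ValueError("negative_binomial noise needs dispersion > 0")

    @property
    def class_counts(self) -> dict:
        g = self.n_genes
        n = {
            "over-dominance": int(np.floor(self.frac_over * g)),
            "under-dominance": int(np.floor(self.frac_under * g)),
            "maternal-ELD": int(np.floor(self.frac_maternal_eld * g)),
            "paternal-ELD": int(np.floor(self.frac_paternal_eld * g)),
            "additive": int(np.floor(self.frac_additive * g)),
        }
        n["none"] = g - sum(n.values())
        return n


@dataclass
class TruthTable:
    """Planted ground truth: per-gene pattern per hybrid, planted direction,
    true mean TPM per library, and (after annotation generation) the
    designated enriched term."""

    table: pd.DataFrame
    config: SimConfig
    planted_term: str | None = None
    planted_term_genes: frozenset = field(default_factory=frozenset)

    def genes_of_class(self, pattern: str, hybrid: str = "AC") -> pd.Index:
        col = f"pattern_{hybrid}"
        return self.table.index[self.table[col] == pattern]


def expected_counts(truth: "TruthTable") -> np.ndarray:
    """Per-cell count expectations of an experiment: proportional to true
    mean TPM, normalized per library to sum to the configured depth."""
    mu = truth.table[[f"tpm_{lib}" for lib in _LIBS]].to_numpy()
    return _expected_counts(mu, truth.config.depth)


def _expected_counts(mu: np.ndarray, depth: int) -> np.ndarray:
    return depth * mu / mu.sum(axis=0, keepdims=True)


def draw_counts(expected: np.ndarray, rng: np.random.Generator,
                noise: str = "poisson", dispersion: float = 0.0
                ) -> np.ndarray:
    """Sample one count matrix around the given expectations."""
    if noise == "poisson":
        return rng.poisson(expected)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, expected * dispersion)
    return rng.poisson(lam)


def generate_experiment(config: SimConfig) -> tuple[CountTable, TruthTable]:
    """Draw one five-library experiment; deterministic given the seed."""
    rng = np.random.default_rng(config.seed)
    g = config.n_genes
    s = config.effect_size
    rho = config.hybrid_separation

    base = rng.lognormal(mean=0.0, sigma=config.baseline_sdlog, size=g)
    base *= 1e6 / base.sum()

    order = rng.permutation(g)
    counts_per_class = config.class_counts
    labels = np.array(["none"] * g, dtype=object)
    direction = np.array(["none"] * g, dtype=object)
    pos = 0
    for cls in ("over-dominance", "under-dominance", "maternal-ELD",
                "paternal-ELD", "additive"):
        n_cls = counts_per_class[cls]
        idx = order[pos:pos + n_cls]
        pos += n_cls
        labels[idx] = cls
        if cls == "over-dominance":
            direction[idx] = "up"
        elif cls == "under-dominance":
            direction[idx] = "down"
        elif cls == "paternal-ELD":
            direction[idx] = "none"
        else:  # maternal-ELD / additive get up and down halves
            half = n_cls // 2
            direction[idx[:half]] = "up"
            direction[idx[half:]] = "down"

    planted = labels != "none"
    lo, hi = config.planted_tpm_range
    base[planted] = rng.uniform(lo, hi, size=int(planted.sum()))

    mu = np.tile(base[:, None], (1, 5)).astype(float)  # AA BB CC AC BC
    aa, bb, cc, ac, bc = range(5)

    # background maternal divergence (hybrids stay at exact mid-parent)
    none_idx = np.flatnonzero(labels == "none")
    divergent = none_idx[rng.random(none_idx.size)
                         > config.shared_maternal_fraction]
    mu[divergent, aa] *= 2.0 ** rng.normal(0, config.maternal_sdlog2,
                                           divergent.size)
    mu[divergent, bb] *= 2.0 ** rng.normal(0, config.maternal_sdlog2,
                                           divergent.size)

    def _rows(cls, d=None):
        hit = labels == cls
        if d is not None:
            hit &= direction == d
        return np.flatnonzero(hit)

    r = _rows("over-dominance")
    mu[r, aa] = base[r]
    mu[r, bb] = rho * base[r]
    mu[r, cc] = rho ** 2 * base[r]
    mu[r, ac] = s * base[r]          # = max(AA, CC) * s
    mu[r, bc] = s * rho * base[r]    # = max(BB, CC) * s

    r = _rows("under-dominance")
    mu[r, aa] = rho * base[r]
    mu[r, bb] = base[r]
    mu[r, cc] = base[r] / rho
    mu[r, ac] = rho * base[r] / s    # = min(AA, CC) / s
    mu[r, bc] = base[r] / s          # = min(BB, CC) / s

    r = _rows("maternal-ELD", "up")
    mu[r, aa] = s * base[r]
    mu[r, bb] = s * rho * base[r]
    mu[r, cc] = base[r]
    mu[r, ac] = mu[r, aa]
    mu[r, bc] = mu[r, bb]

    r = _rows("maternal-ELD", "down")
    mu[r, aa] = base[r] / s
    mu[r, bb] = base[r] / (s * rho)
    mu[r, cc] = base[r]
    mu[r, ac] = mu[r, aa]
    mu[r, bc] = mu[r, bb]

    r = _rows("paternal-ELD")
    mu[r, aa] = s * base[r]
    mu[r, bb] = s * rho * base[r]
    mu[r, cc] = base[r]
    mu[r, ac] = mu[r, cc]
    mu[r, bc] = mu[r, cc]

    r = _rows("additive", "up")
    mu[r, aa] = s * base[r]
    mu[r, bb] = s * rho * base[r]
    mu[r, cc] = base[r]

    r = _rows("additive", "down")
    mu[r, aa] = base[r] / s ** 2
    mu[r, bb] = base[r] / 3
    mu[r, cc] = base[r]

    # all hybrids not yet set explicitly sit at the exact mid-parent value
    free = np.isin(labels, ("none", "additive"))
    mu[free, ac] = (mu[free, aa] + mu[free, cc]) / 2
    mu[free, bc] = (mu[free, bb] + mu[free, cc]) / 2

    expected = _expected_counts(mu, config.depth)
    counts = draw_counts(expected, rng, config.noise, config.dispersion)

    gene_ids = [f"gene_{i:05d}" for i in range(g)]
    frame = pd.DataFrame(counts.astype(np.int64), columns=list(_LIBS),
                         index=pd.Index(gene_ids, name="gene_id"))
    truth = pd.DataFrame({
        "pattern_AC": labels,
        "pattern_BC": labels,
        "direction": direction,
        **{f"tpm_{lib}": mu[:, i] for i, lib in enumerate(_LIBS)},
    }, index=frame.index)
    return CountTable(frame), TruthTable(table=truth, config=config)


def null_config(seed: int = 0, **overrides) -> SimConfig:
    """A fully null configuration: no planted patterns, identical maternal
    lines, so all five libraries share one proportion vector."""
    cfg = SimConfig(frac_over=0.0, frac_under=0.0, frac_maternal_eld=0.0,
                    frac_paternal_eld=0.0, frac_additive=0.0,
                    shared_maternal_fraction=1.0, seed=seed)
    return replace(cfg, **overrides) if overrides else cfg


def generate_annotations(truth: TruthTable, n_terms: int = 40,
                         planted_term_size: int | None = None,
                         seed: int = 0,
                         target_class: str | None = "over-dominance",
                         hit_rate: float = 0.8,
                         background_rate: float = 0.02) -> AnnotationTable:
    """Random gene -> term annotations with one planted enriched term.

    Background terms annotate uniform random gene subsets. The designated
    term (recorded on ``truth.planted_term``) preferentially annotates genes
    of ``target_class`` (a ``hit_rate`` fraction of the class plus a
    ``background_rate`` fraction of other genes); ``target_class=None``
    disables planting and all terms are uniform.
    """
    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    genes = np.asarray(truth.table.index)
    g = genes.size
    if planted_term_size is not None and planted_term_size > g:
        raise ValueError("planted_term_size exceeds the number of genes")
    rng = np.random.default_rng(seed)
    ontologies = ("biological_process", "molecular_function",
                  "cellular_component")
    rows = []
    n_background = n_terms if target_class is None else n_terms - 1
    for i in range(n_background):
        size = int(rng.integers(10, 61))
        members = rng.choice(genes, size=min(size, g), replace=False)
        term = f"GO:{7000000 + i}"
        for m in members:
            rows.append((m, term, ontologies[i % 3], f"synthetic term {i}"))
    planted_genes: frozenset = frozenset()
    planted_term = None
    if target_class is not None:
        in_class = np.asarray(truth.genes_of_class(target_class))
        others = genes[~np.isin(genes, in_class)]
        if planted_term_size is None:
            n_hit = int(round(hit_rate * in_class.size))
            n_bg = int(round(background_rate * others.size))
        else:
            n_hit = min(int(round(0.8 * planted_term_size)), in_class.size)
            n_bg = min(planted_term_size - n_hit, others.size)
        members = np.concatenate([
            rng.choice(in_class, size=n_hit, replace=False)
            if n_hit else in_class[:0],
            rng.choice(others, size=n_bg, replace=False)
            if n_bg else others[:0],
        ])
        planted_term = "GO:7999999"
        for m in members:
            rows.append((m, planted_term, "biological_process",
                         "synthetic planted term"))
        planted_genes = frozenset(members)
    frame = pd.DataFrame(rows, columns=["gene_id", "term_id", "ontology",
                                        "term_name"], dtype=str)
    frame = frame.drop_duplicates(["gene_id", "term_id"]).reset_index(
        drop=True)
    truth.planted_term = planted_term
    truth.planted_term_genes = planted_genes
    return AnnotationTable(frame)
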