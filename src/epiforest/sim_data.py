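"""Synthetic case-control genotype data with planted main and epistatic effects.

Genotypes are drawn in Hardy-Weinberg proportions; the binary phenotype comes
from a logistic model with optional additive main effects and AND/XOR
interaction terms on carrier (dosage >= 1) indicators.  Linkage
disequilibrium is emulated by noisy copies of anchor columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_genotype import GenotypeMatrix, PhenotypeTable, VariantMeta

VALID_MODELS = ("AND", "XOR")


@dataclass
class SimulationSpec:
    n_subjects: int
    n_variants: int
    maf_range: tuple[float, float] = (0.05, 0.5)
    case_fraction: float = 0.29
    main_effects: list[tuple[int, float]] = field(default_factory=list)
    interactions: list[tuple[int, int, str, float]] = field(default_factory=list)
    ld_blocks: list[tuple[int, int, float]] = field(default_factory=list)
    maf_overrides: list[tuple[int, float]] = field(default_factory=list)
    baseline_logit: float | None = None  # None -> calibrated by bisection
    carrier_coding: str = "dominant"     # or "recessive"
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.maf_range
        if not (0.01 <= lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within [0.01, 0.5]")
        if not (0.0 < self.case_fraction < 1.0):
            raise ValueError("case_fraction must be in (0, 1)")
        planted = [i for i, _ in self.main_effects]
        for i, j, model, _ in self.interactions:
            base = model.split(":", 1)[0]
            if base not in VALID_MODELS:
                raise ValueError(f"interaction model must be in {VALID_MODELS}")
            planted += [i, j]
        if len(planted) != len(set(planted)):
            raise ValueError("planted indices must be distinct")
        if any(i < 0 or i >= self.n_variants for i in planted):
            raise ValueError("planted index out of range")
        if self.carrier_coding not in ("dominant", "recessive"):
            raise ValueError("carrier_coding must be dominant or recessive")
        for i, m in self.maf_overrides:
            if not (0.01 <= m <= 0.5):
                raise ValueError("maf override outside [0.01, 0.5]")
            if i < 0 or i >= self.n_variants:
                raise ValueError("maf override index out of range")


@dataclass
class TruthSet:
    """Which variants carry planted signal, for power evaluation."""

    main_indices: list[int]
    pairs: list[tuple[int, int, str]]

    def to_frame(self, variant_ids=None):
        import pandas as pd

        def name(i):
            return variant_ids[i] if variant_ids is not None else i

        rows = [{"kind": "main", "member_1": name(i), "member_2": "", "model": ""}
                for i in self.main_indices]
        rows += [{"kind": "pair", "member_1": name(i), "member_2": name(j),
                  "model": m} for i, j, m in self.pairs]
        return pd.DataFrame(rows, columns=["kind", "member_1", "member_2", "model"])


def _hwe_column(rng, maf, n):
    u = rng.random(n)
    p0 = (1.0 - maf) ** 2
    p1 = 2.0 * maf * (1.0 - maf)
    return ((u >= p0).astype(np.int8) + (u >= p0 + p1).astype(np.int8))


def simulate_genotypes(spec: SimulationSpec) -> GenotypeMatrix:
    """Draw the dosage matrix.  LD-block copies are appended after the base
    ``n_variants`` columns, each equal to its anchor with every subject's
    value independently resampled from the anchor's HWE marginal with the
    block's flip probability.  Deterministic under ``spec.seed``."""
    ss = np.random.SeedSequence([spec.seed, 0])
    rng = np.random.Generator(np.random.PCG64(ss))
    n, p = spec.n_subjects, spec.n_variants
    mafs = rng.uniform(spec.maf_range[0], spec.maf_range[1], size=p)
    for i, m in spec.maf_overrides:
        mafs[i] = m

    X = np.empty((n, p), dtype=np.int8)
    for j in range(p):
        X[:, j] = _hwe_column(rng, mafs[j], n)

    cols = [X]
    metas = [
        VariantMeta(id=f"sim{j:06d}", chrom=str(j % 22 + 1), pos=(j // 22 + 1) * 1000,
                    ref_allele="A", alt_allele="C",
                    maf=float(min(X[:, j].mean() / 2, 1 - X[:, j].mean() / 2)))
        for j in range(p)
    ]
    k = p
    for anchor, n_copies, flip_p in spec.ld_blocks:
        for c in range(n_copies):
            col = X[:, anchor].copy()
            flip = rng.random(n) < flip_p
            if flip.any():
                col[flip] = _hwe_column(rng, mafs[anchor], int(flip.sum()))
            cols.append(col[:, None])
            m = metas[anchor]
            metas.append(VariantMeta(
                id=f"sim{anchor:06d}_ld{c}", chrom=m.chrom, pos=m.pos + c + 1,
                ref_allele="A", alt_allele="C",
                maf=float(min(col.mean() / 2, 1 - col.mean() / 2))))
            k += 1

    dosages = np.concatenate(cols, axis=1) if len(cols) > 1 else X
    # orient any column whose sample minor allele flipped
    freq = dosages.mean(axis=0) / 2.0
    flip_cols = freq > 0.5
    if flip_cols.any():
        dosages = dosages.copy()
        dosages[:, flip_cols] = 2 - dosages[:, flip_cols]
    subject_ids = [f"S{i:06d}" for i in range(n)]
    return GenotypeMatrix(dosages=dosages, variants=metas, subject_ids=subject_ids)


def interaction_indicator(gi, gj, model: str, coding: str = "dominant"):
    """f(model, gi, gj) on carrier indicators.

    AND: 1 iff both loci carry; XOR: 1 iff exactly one carries.
    Dominant coding: carrier = dosage >= 1; recessive: dosage == 2.
    ``model`` may carry an explicit per-interaction coding suffix
    ("XOR:recessive"), overriding ``coding``.
    """
    if ":" in model:
        model, coding = model.split(":", 1)
    if coding not in ("dominant", "recessive"):
        raise ValueError(f"unknown coding {coding!r}")
    if coding == "dominant":
        ci, cj = gi >= 1, gj >= 1
    else:
        ci, cj = gi == 2, gj == 2
    if model == "AND":
        return (ci & cj).astype(np.float64)
    if model == "XOR":
        return (ci ^ cj).astype(np.float64)
    raise ValueError(f"unknown model {model!r}")


def _calibrate_baseline(contrib: np.ndarray, target: float, tol: float = 1e-6):
    """Bisection on b0 so that mean(sigmoid(b0 + contrib)) == target."""

    def realized(b0):
        return float((1.0 / (1.0 + np.exp(-(b0 + contrib)))).mean())

    lo, hi = -40.0, 40.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if realized(mid) < target:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)


def simulate_phenotype(gm: GenotypeMatrix, spec: SimulationSpec) -> PhenotypeTable:
    """Draw case/control status from the planted logistic model.

    P(case) = sigmoid(b0 + sum beta*dosage + sum gamma*f(model, gi, gj)).
    When ``spec.baseline_logit`` is None, b0 is calibrated by bisection so
    the expected case fraction matches ``spec.case_fraction`` (the realized
    fraction is then within sampling noise, ±0.02 at the spec's scales).
    """
    X = gm.dosages
    contrib = np.zeros(gm.n_subjects)
    for idx, beta in spec.main_effects:
        contrib += beta * X[:, idx]
    for i, j, model, gamma in spec.interactions:
        contrib += gamma * interaction_indicator(
            X[:, i], X[:, j], model, spec.carrier_coding)
    if not np.all(np.isfinite(contrib)):
        raise ValueError("non-finite logit contribution")

    b0 = (spec.baseline_logit if spec.baseline_logit is not None
          else _calibrate_baseline(contrib, spec.case_fraction))
    prob = 1.0 / (1.0 + np.exp(-(b0 + contrib)))
    if not np.all(np.isfinite(prob)):
        raise ValueError("non-finite case probability")

    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([spec.seed, 1])))
    status = (rng.random(gm.n_subjects) < prob).astype(np.int8)
    # guarantee both classes so downstream contracts hold even at tiny n
    if status.min() == status.max():
        status[0] = 1 - status[0]
    return PhenotypeTable(subject_ids=list(gm.subject_ids), status=status)


def truth_set(spec: SimulationSpec) -> TruthSet:
    return TruthSet(
        main_indices=[i for i, _ in spec.main_effects],
        pairs=[(i, j, m) for i, j, m, _ in spec.interactions],
    )


def simulate(spec: SimulationSpec):
    """Convenience wrapper: (GenotypeMatrix, PhenotypeTable, TruthSet)."""
    gm = simulate_genotypes(spec)
    pheno = simulate_phenotype(gm, spec)
    return gm, pheno, truth_set(spec)
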