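"""Additive/dominance effect estimation and dominance classification.

At a locus with genotype classes AA/Aa/aa (A = Zhenshan 97 allele), the
additive effect is half the difference between the homozygote means,
a = (m_AA - m_aa) / 2, and the dominance deviation is the heterozygote mean
minus the homozygote midpoint, d = m_Aa - (m_AA + m_aa) / 2. Dominance
significance is assessed by permuting residuals of the additive-only fit
(the h-test); significant negative d with the heterozygote below both
homozygotes (d < -|a|) is negative overdominance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DOMINANCE_CLASSES = (
    "none",
    "positive",
    "negative",
    "positive-overdominant",
    "negative-overdominant",
)


@dataclass
class EffectEstimate:
    """Group means plus the derived additive/dominance effects.

    ``d`` is NaN when the heterozygote class is absent.
    """

    m_AA: float
    m_Aa: float
    m_aa: float
    a: float
    d: float
    n_AA: int
    n_Aa: int
    n_aa: int

    @property
    def d_defined(self) -> bool:
        return not np.isnan(self.d)


def estimate_effects(values, dosage) -> EffectEstimate:
    """Unweighted within-class means; positive a means the Zhenshan 97
    homozygote expresses higher."""
    y = np.asarray(values, dtype=float)
    g = np.asarray(dosage)
    means, ns = [], []
    for k in (2, 1, 0):  # AA, Aa, aa
        sel = g == k
        ns.append(int(sel.sum()))
        means.append(float(y[sel].mean()) if sel.any() else np.nan)
    m_AA, m_Aa, m_aa = means
    if np.isnan(m_AA) or np.isnan(m_aa):
        raise ValueError("both homozygote classes are required")
    a = (m_AA - m_aa) / 2.0
    d = m_Aa - (m_AA + m_aa) / 2.0 if not np.isnan(m_Aa) else np.nan
    return EffectEstimate(m_AA, m_Aa, m_aa, a, d, *ns)


def h_test(
    values,
    dosage,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
) -> float:
    """Permutation test of the dominance deviation d.

    The additive-only model y ~ 1 + x (x in {-1, 0, +1}) is fitted by least
    squares; its residuals are permuted and added back to the fitted values,
    and d is recomputed each time. Because d of the fitted values is exactly
    zero, the null d equals a permuted-residual contrast, which isolates
    dominance from additive signal. Two-sided p with the +1 correction.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    y = np.asarray(values, dtype=float)
    g = np.asarray(dosage)
    n_by_class = [(g == k).sum() for k in (0, 1, 2)]
    if min(n_by_class) == 0:
        raise ValueError("h-test requires all three genotype classes")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    x = g.astype(float) - 1.0
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    # d is a linear contrast c'y with weights 1/n_Aa, -1/(2 n_AA), -1/(2 n_aa).
    c = np.empty_like(y)
    c[g == 1] = 1.0 / n_by_class[1]
    c[g == 2] = -0.5 / n_by_class[2]
    c[g == 0] = -0.5 / n_by_class[0]
    d_obs = float(c @ y)
    perms = rng.permuted(
        np.broadcast_to(resid, (n_perm, len(resid))), axis=1
    )
    d_null = perms @ c
    return float((1 + np.sum(np.abs(d_null) >= abs(d_obs))) / (1 + n_perm))


def classify_dominance(est: EffectEstimate, significant: bool) -> str:
    """Dominance class from the sign and magnitude of d.

    Non-significant d is "none". Significant d < 0 is negative dominance
    (heterozygote below the mid-parent value); d < -|a| additionally puts
    the heterozygote below both homozygotes: negative overdominance.
    Mirrored for positive d.
    """
    if not est.d_defined:
        raise ValueError("dominance undefined (no heterozygotes)")
    if not significant or est.d == 0:
        return "none"
    if est.d < 0:
        return "negative-overdominant" if est.d < -abs(est.a) else "negative"
    return "positive-overdominant" if est.d > abs(est.a) else "positive"
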