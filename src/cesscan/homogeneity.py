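"""Phenotypic homogeneity of subcohort sampling.

If a composite trio cohort is recruited uniformly, the subcohort of
origin of each de novo LoF variant in a gene is multinomial with
probabilities proportional to each subcohort's mutational capacity —
measured by its synonymous de novo count.  Departures are detected by
comparing four models with AIC:

1. multinomial, probabilities fixed at synonymous proportions (0 free
   parameters);
2. multinomial, free probabilities (C-1 parameters);
3. Dirichlet-multinomial centred on the synonymous proportions, free
   concentration (1 parameter) — gene-level overdispersion;
4. Dirichlet-multinomial with free mean and concentration (C
   parameters).

Model 1 preferred by AIC is the signature of uniform sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special

__all__ = [
    "CohortCountMatrix",
    "HomogeneityFit",
    "loglik_fixed_multinomial",
    "fit_free_multinomial",
    "fit_dirichlet_multinomial",
    "compare_homogeneity",
]

CONC_LOWER = 1e-3
CONC_UPPER = 1e6


@dataclass
class CohortCountMatrix:
    """Gene-by-subcohort de novo count matrix with synonymous weights."""

    counts: np.ndarray  # (G, C) nonnegative integers
    weights: np.ndarray  # (C,) positive reals (synonymous counts)
    subcohorts: list = field(default_factory=list)

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-d gene x subcohort matrix")
        if self.counts.shape[1] != self.weights.shape[0]:
            raise ValueError("weights length must equal number of subcohorts")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        if np.any(self.weights < 0) or self.weights.sum() <= 0:
            raise ValueError("weights must be nonnegative with positive sum")
        if not self.subcohorts:
            self.subcohorts = [f"c{i}" for i in range(self.counts.shape[1])]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_subcohorts(self) -> int:
        return self.counts.shape[1]

    @property
    def weight_proportions(self) -> np.ndarray:
        return self.weights / self.weights.sum()


def _multinomial_loglik(counts: np.ndarray, p: np.ndarray) -> float:
    """Sum over rows of the multinomial log-pmf at probabilities ``p``.

    Rows with zero total contribute 0.  A positive count in a
    zero-probability category makes the log-likelihood -inf.
    """
    counts = np.asarray(counts, dtype=np.int64)
    p = np.asarray(p, dtype=float)
    if np.any((p == 0) & (counts.sum(axis=0) > 0)):
        return -np.inf
    n = counts.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = np.where(p > 0, np.log(p), 0.0)
    ll = (
        special.gammaln(n + 1)
        - special.gammaln(counts + 1).sum(axis=1)
        + (counts * logp).sum(axis=1)
    )
    return float(ll.sum())


def _dirmult_loglik(counts: np.ndarray, p: np.ndarray, conc: float) -> float:
    """Sum over rows of the Dirichlet-multinomial log-pmf, alpha = conc*p."""
    if conc <= 0:
        raise ValueError("concentration must be > 0")
    counts = np.asarray(counts, dtype=np.int64)
    alpha = conc * np.asarray(p, dtype=float)
    if np.any((alpha == 0) & (counts.sum(axis=0) > 0)):
        return -np.inf
    pos = alpha > 0
    n = counts.sum(axis=1)
    a0 = alpha.sum()
    ll = (
        special.gammaln(n + 1)
        - special.gammaln(counts + 1).sum(axis=1)
        + special.gammaln(a0)
        - special.gammaln(n + a0)
        + (
            special.gammaln(counts[:, pos] + alpha[pos])
            - special.gammaln(alpha[pos])
        ).sum(axis=1)
    )
    return float(ll.sum())


def loglik_fixed_multinomial(matrix: CohortCountMatrix) -> float:
    """Model 1: multinomial with probabilities fixed at synonymous
    proportions."""
    return _multinomial_loglik(matrix.counts, matrix.weight_proportions)


def fit_free_multinomial(matrix: CohortCountMatrix):
    """Model 2: multinomial MLE.

    Returns ``(probabilities, loglik)``; the MLE pools counts across
    genes (column sums over the grand total).
    """
    if matrix.n_subcohorts < 2:
        raise ValueError("need >= 2 subcohorts")
    total = matrix.counts.sum()
    if total == 0:
        raise ValueError("grand total is zero: probabilities undefined")
    p_hat = matrix.counts.sum(axis=0) / total
    return p_hat, _multinomial_loglik(matrix.counts, p_hat)


def _fit_concentration(counts: np.ndarray, p: np.ndarray):
    """1-d bounded MLE of the Dirichlet concentration at fixed mean ``p``.

    Returns ``(conc, loglik)``; the multinomial limit (conc -> inf) is a
    candidate, reported as ``np.inf``, which keeps the nesting
    inequality 'DM fit >= multinomial fit' exact.
    """

    def neg(log_conc: float) -> float:
        return -_dirmult_loglik(counts, p, np.exp(log_conc))

    res = optimize.minimize_scalar(
        neg,
        bounds=(np.log(CONC_LOWER), np.log(CONC_UPPER)),
        method="bounded",
        options={"xatol": 1e-9},
    )
    conc, ll = float(np.exp(res.x)), -float(res.fun)
    ll_limit = _multinomial_loglik(counts, p)
    if ll_limit >= ll:
        return np.inf, ll_limit
    return conc, ll


def fit_dirichlet_multinomial(matrix: CohortCountMatrix, center: str = "fixed"):
    """Models 3 and 4: Dirichlet-multinomial fits.

    Parameters
    ----------
    center
        ``"fixed"`` — Dirichlet mean pinned to the synonymous
        proportions, concentration free (model 3).
        ``"free"`` — mean and concentration both free (model 4).

    Returns
    -------
    (concentration, probabilities, loglik)
    """
    counts = matrix.counts
    p_fixed = matrix.weight_proportions
    if center == "fixed":
        conc, ll = _fit_concentration(counts, p_fixed)
        return conc, p_fixed, ll
    if center != "free":
        raise ValueError("center must be 'fixed' or 'free'")

    # model 4: joint optimisation over (log concentration, mean logits),
    # initialised at the free-multinomial MLE and the model-3 concentration
    p2, ll2 = fit_free_multinomial(matrix)
    conc3, _, ll3 = fit_dirichlet_multinomial(matrix, center="fixed")
    C = matrix.n_subcohorts
    p_init = np.clip(p2, 1e-6, None)
    p_init = p_init / p_init.sum()
    logits0 = np.log(p_init[:-1]) - np.log(p_init[-1])
    conc0 = conc3 if np.isfinite(conc3) else 100.0

    def unpack(theta):
        conc = np.exp(theta[0])
        z = np.concatenate([theta[1:], [0.0]])
        z = z - z.max()
        p = np.exp(z)
        return conc, p / p.sum()

    def neg(theta):
        conc, p = unpack(theta)
        val = _dirmult_loglik(counts, p, conc)
        return np.inf if not np.isfinite(val) else -val

    theta0 = np.concatenate([[np.log(conc0)], logits0])
    bounds = [(np.log(CONC_LOWER), np.log(CONC_UPPER))] + [(-30, 30)] * (C - 1)
    res = optimize.minimize(neg, theta0, method="L-BFGS-B", bounds=bounds)
    cand = []
    if np.isfinite(res.fun):
        conc4, p4 = unpack(res.x)
        cand.append((conc4, p4, -float(res.fun)))
    # limits that model 4 nests: free multinomial (conc -> inf), model 3,
    # and the fixed multinomial; including them keeps the nesting chain
    # model4 >= model3 >= model1 exact regardless of optimiser noise
    cand.append((np.inf, p2, ll2))
    cand.append((conc3, p_fixed, ll3))
    cand.append((np.inf, p_fixed, loglik_fixed_multinomial(matrix)))
    best = max(cand, key=lambda t: t[2])
    return best


MODEL_N_PARAMS = {
    "m1_fixed_multinomial": lambda C: 0,
    "m2_free_multinomial": lambda C: C - 1,
    "m3_dirmult_fixed_center": lambda C: 1,
    "m4_dirmult_free": lambda C: C,
}


@dataclass
class HomogeneityFit:
    """Per-model likelihoods, AIC values, and the AIC-preferred model."""

    models: dict  # name -> {"loglik", "n_params", "aic", ...}
    best_model: str
    warnings: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "models": self.models,
            "best_model": self.best_model,
            "warnings": self.warnings,
        }


def compare_homogeneity(matrix: CohortCountMatrix) -> HomogeneityFit:
    """Fit all four sampling models and select by AIC (2k - 2 logL)."""
    C = matrix.n_subcohorts
    warnings = []
    if matrix.n_genes < 2:
        warnings.append(
            "fewer than 2 genes: Dirichlet concentration is unidentifiable"
        )

    ll1 = loglik_fixed_multinomial(matrix)
    p2, ll2 = fit_free_multinomial(matrix)
    conc3, _, ll3 = fit_dirichlet_multinomial(matrix, center="fixed")
    conc4, p4, ll4 = fit_dirichlet_multinomial(matrix, center="free")

    models = {
        "m1_fixed_multinomial": {"loglik": ll1},
        "m2_free_multinomial": {"loglik": ll2, "probabilities": p2.tolist()},
        "m3_dirmult_fixed_center": {"loglik": ll3, "concentration": conc3},
        "m4_dirmult_free": {
            "loglik": ll4,
            "concentration": conc4,
            "probabilities": np.asarray(p4).tolist(),
        },
    }
    for name, info in models.items():
        k = MODEL_N_PARAMS[name](C)
        info["n_params"] = k
        info["aic"] = 2.0 * k - 2.0 * info["loglik"]
    best = min(models, key=lambda name: models[name]["aic"])
    return HomogeneityFit(models=models, best_model=best, warnings=warnings)
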