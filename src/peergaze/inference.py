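"""Information-theoretic mixed-model analysis of interpretation ratings.

Workflow:

1. assemble one row per QC-retained trial (rating on the 0-100 scale;
   perspective and valence effect-coded -0.5/+0.5; fixation time and the
   individual-differences covariate — social anxiety or age — z-scored);
2. fit the global crossed random-intercepts model and every marginality-
   closed subset of its 15 fixed-effect terms by maximum likelihood
   (167 candidates for the 4-factor global model);
3. convert AICs to Akaike weights w_i = exp(-Delta_i/2) / sum exp(-Delta_j/2);
4. average coefficients across candidates.  Full averaging substitutes 0 for
   a term absent from a model; the unconditional standard error follows
   Burnham & Anderson, SE_bar = sum_i w_i sqrt(SE_i^2 + (theta_i -
   theta_bar)^2); 95% CIs are theta_bar +- 1.96 SE_bar with p-values from the
   normal approximation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .lmm import CrossedLMMWorkspace, LMMFit

logger = logging.getLogger(__name__)

__all__ = [
    "AveragedCoefficient",
    "ModelAveragingResult",
    "model_factors",
    "global_terms",
    "term_name",
    "code_predictors",
    "build_model_table",
    "design_matrix",
    "enumerate_candidates",
    "akaike_weights",
    "model_average",
    "run_analysis",
]

Z95 = 1.96

FACTOR_LEVELS = {
    "perspective": ("other", "self"),   # coded -0.5 / +0.5
    "valence": ("negative", "positive"),
}


def model_factors(which: str) -> tuple[str, ...]:
    """Canonical fixed-effect factor order for one of the two model families."""
    if which not in ("anxiety", "age"):
        raise ValueError("which must be 'anxiety' or 'age'")
    return ("perspective", "valence", "fixation", which)


def global_terms(factors: tuple[str, ...]) -> list[tuple[str, ...]]:
    """All main effects and interactions, low order first, deterministic."""
    terms: list[tuple[str, ...]] = []
    n = len(factors)
    for size in range(1, n + 1):
        from itertools import combinations
        terms.extend(combinations(factors, size))
    return terms


def term_name(term: tuple[str, ...]) -> str:
    return ":".join(term)


def _zscore(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, float)
    sd = x.std()
    if sd == 0:
        raise ValueError("cannot z-score a constant predictor")
    return (x - x.mean()) / sd


def code_predictors(design: pd.DataFrame, fixation_time_ms: np.ndarray,
                    which: str) -> pd.DataFrame:
    """Numeric predictor table: factors at -0.5/+0.5, continuous z-scored."""
    n = len(design)
    fixation_time_ms = np.asarray(fixation_time_ms, float)
    if len(fixation_time_ms) != n:
        raise ValueError("fixation-time column must align with design rows")
    rec = pd.DataFrame(index=np.arange(n))
    for col in ("perspective", "valence"):
        lo, hi = FACTOR_LEVELS[col]
        vals = design[col].astype(str).to_numpy()
        bad = set(vals) - {lo, hi}
        if bad:
            raise ValueError(f"unknown {col} levels {sorted(bad)}")
        rec[col] = np.where(vals == hi, 0.5, -0.5)
    rec["fixation"] = _zscore(fixation_time_ms)
    if which not in design.columns:
        raise ValueError(f"design lacks covariate column {which!r}")
    rec[which] = _zscore(design[which].to_numpy())
    rec["subject_id"] = design["participant_id"].to_numpy()
    rec["scene_id"] = design["scene_id"].to_numpy()
    return rec


def build_model_table(metrics: pd.DataFrame, ratings: pd.DataFrame,
                      participants: pd.DataFrame, which: str) -> pd.DataFrame:
    """Join per-trial AOI metrics, ratings and participant covariates into
    the modelling table (one row per QC-retained trial).

    ``metrics`` needs trial_id, participant_id, scene_id, perspective,
    valence, total_aoi_fixation_ms; ``ratings`` trial_id, rating;
    ``participants`` participant_id plus the covariate column.
    """
    if which not in ("anxiety", "age"):
        raise ValueError("which must be 'anxiety' or 'age'")
    m = metrics.merge(ratings[["trial_id", "rating"]], on="trial_id",
                      how="left", validate="one_to_one")
    if m["rating"].isna().any():
        missing = m.loc[m["rating"].isna(), "trial_id"].tolist()
        raise ValueError(f"trials without ratings: {missing[:10]}")
    m = m.merge(participants[["participant_id", which]], on="participant_id",
                how="left", validate="many_to_one")
    if m[which].isna().any():
        missing = sorted(set(m.loc[m[which].isna(), "participant_id"]))
        raise ValueError(f"participants without {which}: {missing[:10]}")
    rec = code_predictors(m, m["total_aoi_fixation_ms"].to_numpy(), which)
    rec.insert(0, "rating", m["rating"].to_numpy())
    rec["trial_id"] = m["trial_id"].to_numpy()
    return rec


def design_matrix(records: pd.DataFrame, terms: list[tuple[str, ...]],
                  factors: tuple[str, ...]) -> np.ndarray:
    """Fixed-effect design matrix: intercept column then one product column
    per term, in the given order."""
    n = len(records)
    X = np.ones((n, 1 + len(terms)))
    for j, term in enumerate(terms, start=1):
        col = np.ones(n)
        for f in term:
            col = col * records[f].to_numpy()
        X[:, j] = col
    return X


def enumerate_candidates(factors: tuple[str, ...]) -> list[tuple[tuple[str, ...], ...]]:
    """All marginality-closed subsets of the global term set.

    A candidate may contain an interaction only if it contains every
    lower-order term nested in it; the intercept-only model is the empty
    tuple.  Terms are visited low order first, so closure can be checked
    incrementally; the output order is deterministic.
    """
    terms = global_terms(factors)
    out: list[tuple[tuple[str, ...], ...]] = []

    def extend(i: int, current: list[tuple[str, ...]], members: set) -> None:
        if i == len(terms):
            out.append(tuple(current))
            return
        extend(i + 1, current, members)
        t = terms[i]
        from itertools import combinations
        needed = [s for size in range(1, len(t))
                  for s in combinations(t, size)]
        if all(s in members for s in needed):
            members.add(t)
            current.append(t)
            extend(i + 1, current, members)
            current.pop()
            members.remove(t)

    extend(0, [], set())
    out.sort(key=lambda c: (len(c), [terms.index(t) for t in c]))
    return out


def akaike_weights(aics: np.ndarray) -> np.ndarray:
    """w_i = exp(-(AIC_i - AIC_min)/2), normalised to sum to 1."""
    aics = np.asarray(aics, float)
    finite = np.isfinite(aics)
    if not finite.any():
        raise ValueError("no finite AIC values")
    w = np.zeros_like(aics)
    delta = aics[finite] - aics[finite].min()
    ww = np.exp(-delta / 2.0)
    w[finite] = ww / ww.sum()
    return w


@dataclass(frozen=True)
class AveragedCoefficient:
    term: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    significant: bool
    weight_sum: float  # summed weight of candidates containing the term


@dataclass
class ModelAveragingResult:
    coefficients: list[AveragedCoefficient]
    weights: np.ndarray
    candidates: pd.DataFrame  # terms, k, loglik, aic, weight
    n_candidates: int

    def table(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "term": c.term, "estimate": c.estimate, "se": c.se,
            "ci_low": c.ci_low, "ci_high": c.ci_high, "p": c.p_value,
            "significant": c.significant, "weight_sum": c.weight_sum,
        } for c in self.coefficients])


def model_average(candidate_terms: list[tuple[tuple[str, ...], ...]],
                  fits: list[LMMFit], weights: np.ndarray,
                  all_terms: list[tuple[str, ...]],
                  conditional: bool = False) -> ModelAveragingResult:
    """Akaike-weight coefficient averaging across candidate models.

    Full averaging (default) substitutes estimate 0 (and SE 0) for terms a
    candidate omits; conditional averaging renormalises weights over the
    models that contain the term.
    """
    if not (len(candidate_terms) == len(fits) == len(weights)):
        raise ValueError("candidates, fits and weights must align")
    weights = np.asarray(weights, float)
    rows = ["intercept"] + [term_name(t) for t in all_terms]
    # per-candidate coefficient lookup
    coef: dict[str, list[tuple[float, float, float]]] = {r: [] for r in rows}
    for terms, fit, w in zip(candidate_terms, fits, weights):
        names = ["intercept"] + [term_name(t) for t in terms]
        lut = {nm: (fit.beta[i], fit.se[i]) for i, nm in enumerate(names)}
        for r in rows:
            th, se = lut.get(r, (0.0, 0.0))
            coef[r].append((w, th, se) if r in lut else (w, 0.0, -1.0))

    out = []
    for r in rows:
        entries = coef[r]
        w_in = sum(w for w, _, se in entries if se >= 0)
        if conditional and r != "intercept":
            sel = [(w, th, se) for w, th, se in entries if se >= 0]
            tot = sum(w for w, _, _ in sel)
            if tot == 0:
                out.append(AveragedCoefficient(r, 0.0, 0.0, 0.0, 0.0, 1.0,
                                               False, 0.0))
                continue
            entries = [(w / tot, th, se) for w, th, se in sel]
        theta_bar = sum(w * th for w, th, _ in entries)
        se_bar = sum(w * np.sqrt(max(se, 0.0) ** 2 + (th - theta_bar) ** 2)
                     for w, th, se in entries)
        lo, hi = theta_bar - Z95 * se_bar, theta_bar + Z95 * se_bar
        if se_bar > 0:
            p = 2.0 * float(norm.sf(abs(theta_bar) / se_bar))
        else:
            p = 0.0 if theta_bar != 0 else 1.0
        out.append(AveragedCoefficient(r, float(theta_bar), float(se_bar),
                                       float(lo), float(hi), p,
                                       not (lo <= 0.0 <= hi), float(w_in)))
    cand_df = pd.DataFrame({
        "terms": [" + ".join(term_name(t) for t in ts) or "(intercept)"
                  for ts in candidate_terms],
        "k": [f.k for f in fits],
        "loglik": [f.loglik for f in fits],
        "aic": [f.aic for f in fits],
        "weight": weights,
    })
    return ModelAveragingResult(out, weights, cand_df, len(fits))


def run_analysis(records: pd.DataFrame, which: str,
                 conditional: bool = False) -> ModelAveragingResult:
    """All-subsets fit + Akaike averaging for one model family.

    ``records`` is the coded table from :func:`build_model_table`.
    Non-converged candidates are dropped with a warning before weighting.
    """
    factors = model_factors(which)
    terms = global_terms(factors)
    X = design_matrix(records, terms, factors)
    ws = CrossedLMMWorkspace(records["rating"].to_numpy(), X,
                             records["subject_id"].to_numpy(),
                             records["scene_id"].to_numpy())
    # the global fit's variance-ratio optimum warm-starts every candidate
    global_fit = ws.fit(np.arange(X.shape[1]))
    start = ws.last_opt if global_fit.converged else None
    kept_terms: list[tuple[tuple[str, ...], ...]] = []
    fits: list[LMMFit] = []
    for cand in enumerate_candidates(factors):
        cols = np.array([0] + [1 + terms.index(t) for t in cand], dtype=int)
        fit = ws.fit(cols, start=start)
        if not fit.converged or not np.isfinite(fit.aic):
            logger.warning("candidate %s did not converge; dropped",
                           [term_name(t) for t in cand])
            continue
        kept_terms.append(cand)
        fits.append(fit)
    if not fits:
        raise RuntimeError("no candidate model converged")
    w = akaike_weights(np.array([f.aic for f in fits]))
    return model_average(kept_terms, fits, w, terms, conditional=conditional)
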