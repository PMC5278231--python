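"""Oxidative balance score (OBS) construction.

The OBS combines seven a-priori pro-/antioxidant exposures: three prooxidants
(total iron intake, smoking, alcohol) and four antioxidants (vitamin C,
retinol, carotene, physical activity).  Continuous exposures are cut at
cohort tertiles and scored 0-2; prooxidants are scored opposite to
antioxidants, so a higher score always means antioxidant predominance:

    iron       2 = low tertile ... 0 = high tertile
    vitamin C, retinol, carotene, activity   0 = low ... 2 = high
    smoking    2 = never, 1 = former, 0 = current
    alcohol    0 = heavy (>= 50 g/day), 2 = otherwise

Component scores are combined under three weighting schemes: equal weights
(plain sum, range 0-14), beta-coefficient weights (-1 x the coefficients of
one multivariable logistic model of MetS on all seven scores, adjusted for
age, sex, area and BMI), and PCA weights (loadings of the first retained
principal component of the standardized scores).  Each continuous score is
cut into cohort quartiles with Q1 (prooxidant predominance) as reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm

ANTIOXIDANT_EXPOSURES = ["vitamin_c", "retinol", "carotene", "activity_met_day"]
TERTILE_EXPOSURES = ["iron", *ANTIOXIDANT_EXPOSURES]
# alcohol is cut at an absolute clinical threshold (g/day) and physical
# activity is roughly symmetric, so neither is log-transformed
LOG_EXPOSURES = ["iron", "vitamin_c", "retinol", "carotene"]

SCORE_COLUMNS = ["iron_score", "vitc_score", "retinol_score",
                 "carotene_score", "activity_score", "smoking_score",
                 "alcohol_score"]
ANTIOXIDANT_SCORES = ["vitc_score", "retinol_score", "carotene_score",
                      "activity_score"]

EXPOSURE_TO_SCORE = {
    "iron": "iron_score",
    "vitamin_c": "vitc_score",
    "retinol": "retinol_score",
    "carotene": "carotene_score",
    "activity_met_day": "activity_score",
}

SMOKING_LEVELS = {"never": 2, "former": 1, "current": 0}

ALCOHOL_HEAVY_CUTOFF = 50.0   # g/day; heavy drinkers score 0
EQUAL_WEIGHT_MAX = 14

QUARTILE_LABELS = ["Q1", "Q2", "Q3", "Q4"]


class DegenerateDistributionError(ValueError):
    """Quantile cutpoints collapsed; the exposure cannot be categorized."""


@dataclass(frozen=True)
class TertileCutpoints:
    """Per-component lower/upper tertile cutpoints, from the analysis cohort."""

    cutpoints: Mapping[str, tuple[float, float]]

    def __getitem__(self, component: str) -> tuple[float, float]:
        return self.cutpoints[component]


@dataclass(frozen=True)
class OBSWeights:
    scheme: str                       # equal | beta | pca
    weights: pd.Series                # indexed by SCORE_COLUMNS
    provenance: dict = field(default_factory=dict)


@dataclass(frozen=True)
class OBSResult:
    scheme: str
    score: pd.Series                  # continuous score per participant
    quartile: pd.Series               # categorical Q1..Q4
    weights: OBSWeights


# ---------------------------------------------------------------------------
# transforms and cutpoints
# ---------------------------------------------------------------------------

def log_transform_components(cohort: pd.DataFrame, *,
                             offset: float = 0.0) -> pd.DataFrame:
    """Natural-log transform the skewed OBS nutrient exposures.

    Applies ``log(x + offset)`` to the tertile-scored nutrient intakes.
    Physical activity is left untouched (approximately symmetric), and
    alcohol is left on its raw scale because its scoring threshold is an
    absolute clinical cut in g/day.  Tertile membership is rank-based, so
    this transform cannot change any component score; it matters for
    analyses that use the continuous exposures directly.  Raises on negative
    exposures or on zeros with a zero offset.
    """
    out = cohort.copy()
    for col in LOG_EXPOSURES:
        if col not in out.columns:
            continue
        vals = out[col].astype(float)
        if (vals < 0).any():
            raise ValueError(f"negative values in exposure column {col!r}")
        shifted = vals + offset
        if (shifted <= 0).any():
            raise ValueError(
                f"column {col!r} contains zeros; pass a positive offset")
        out[col] = np.log(shifted)
    return out


def compute_tertiles(values: pd.Series | np.ndarray) -> tuple[float, float]:
    """Empirical tertile cutpoints (type-7 linear interpolation).

    Membership downstream is lower-inclusive: (-inf, t1], (t1, t2], (t2, inf).
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if len(np.unique(arr)) < 3:
        raise DegenerateDistributionError(
            "need at least 3 distinct values for tertiles")
    t1, t2 = np.quantile(arr, [1 / 3, 2 / 3])
    if t1 == t2:
        raise DegenerateDistributionError(
            f"tertile cutpoints coincide at {t1}")
    return float(t1), float(t2)


def compute_all_cutpoints(cohort: pd.DataFrame) -> TertileCutpoints:
    """Tertile cutpoints for the five tertile-scored exposures."""
    cuts = {col: compute_tertiles(cohort[col]) for col in TERTILE_EXPOSURES}
    return TertileCutpoints(cuts)


def _tertile_category(values: np.ndarray, cuts: tuple[float, float]) -> np.ndarray:
    # 0 = low, 1 = medium, 2 = high; lower-inclusive bins
    return np.searchsorted(np.asarray(cuts), values, side="left")


# ---------------------------------------------------------------------------
# component scoring (Table-2-style assignment)
# ---------------------------------------------------------------------------

def score_components(cohort: pd.DataFrame, cutpoints: TertileCutpoints, *,
                     alcohol_cutoff: float = ALCOHOL_HEAVY_CUTOFF,
                     heavy_alcohol_score: int = 0) -> pd.DataFrame:
    """Assign the seven 0-2 component scores.

    Antioxidants ascend with tertile; iron descends (prooxidant); smoking is
    never=2 / former=1 / current=0; alcohol is binary with heavy drinkers
    (>= ``alcohol_cutoff`` g/day) scoring ``heavy_alcohol_score`` and everyone
    else the opposite end (2 or 0).
    """
    scores = pd.DataFrame(index=cohort.index)
    for exposure, score_col in EXPOSURE_TO_SCORE.items():
        cat = _tertile_category(cohort[exposure].to_numpy(dtype=float),
                                cutpoints[exposure])
        if exposure == "iron":
            scores[score_col] = 2 - cat
        else:
            scores[score_col] = cat

    smoking = cohort["smoking"]
    unknown = set(smoking.unique()) - set(SMOKING_LEVELS)
    if unknown:
        raise ValueError(f"unknown smoking categories: {sorted(unknown)}")
    scores["smoking_score"] = smoking.map(SMOKING_LEVELS).astype(int)

    heavy = cohort["alcohol_g_day"].to_numpy(dtype=float) >= alcohol_cutoff
    nonheavy_score = 2 - heavy_alcohol_score
    scores["alcohol_score"] = np.where(heavy, heavy_alcohol_score,
                                       nonheavy_score)
    return scores[SCORE_COLUMNS]


# ---------------------------------------------------------------------------
# weighting schemes
# ---------------------------------------------------------------------------

def equal_weight_obs(scores: pd.DataFrame) -> OBSResult:
    """Plain sum of the seven component scores (range 0-14)."""
    _check_scores(scores)
    total = scores[SCORE_COLUMNS].sum(axis=1).astype(float)
    weights = OBSWeights("equal", pd.Series(1.0, index=SCORE_COLUMNS))
    return OBSResult("equal", total, assign_quartiles(total), weights)


def beta_weight_obs(scores: pd.DataFrame, covariates: pd.DataFrame,
                    outcome: pd.Series) -> OBSResult:
    """Beta-coefficient weighted OBS.

    Fits one multivariable logistic model of the binary outcome (MetS) on all
    seven component scores plus the adjustment covariates (age, sex, area,
    BMI); the weight of component j is -1 x its fitted coefficient, so
    components inversely associated with disease get positive weight.  The
    continuous score is the weighted sum of the component scores.
    """
    _check_scores(scores)
    if not covariates.index.equals(scores.index):
        raise ValueError("scores and covariates must be row-aligned")
    X = pd.concat([scores[SCORE_COLUMNS], covariates], axis=1).astype(float)
    X = sm.add_constant(X, has_constant="add")
    try:
        fit = sm.Logit(outcome.astype(float), X).fit(disp=0, maxiter=100)
    except Exception as exc:  # PerfectSeparationError and friends
        raise RuntimeError(f"beta-weight logistic model failed: {exc}") from exc
    if not fit.mle_retvals.get("converged", False):
        raise RuntimeError("beta-weight logistic model did not converge")
    weights = -fit.params[SCORE_COLUMNS]
    score = scores[SCORE_COLUMNS].to_numpy() @ weights.to_numpy()
    score = pd.Series(score, index=scores.index)
    wobj = OBSWeights("beta", weights,
                      provenance={"coefficients": fit.params.to_dict(),
                                  "n": int(fit.nobs)})
    return OBSResult("beta", score, assign_quartiles(score), wobj)


def pca_weight_obs(scores: pd.DataFrame) -> OBSResult:
    """PCA-weighted OBS.

    Components are standardized; the eigendecomposition of their correlation
    matrix is taken; PCs with eigenvalue > 1 are retained and the first
    (largest-eigenvalue) retained PC supplies the loadings.  Loadings are
    sign-oriented so the mean loading of the four antioxidant components is
    positive; the score is the loading-weighted sum of standardized scores.
    """
    _check_scores(scores)
    if len(scores) < len(SCORE_COLUMNS):
        raise ValueError("need at least as many participants as components")
    arr = scores[SCORE_COLUMNS].to_numpy(dtype=float)
    sd = arr.std(axis=0, ddof=1)
    if (sd == 0).any():
        dead = [c for c, s in zip(SCORE_COLUMNS, sd) if s == 0]
        raise DegenerateDistributionError(
            f"zero-variance component scores: {dead}")
    z = (arr - arr.mean(axis=0)) / sd
    corr = np.corrcoef(z, rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    retained = int(np.sum(eigval > 1.0))
    retained = max(retained, 1)   # always keep at least the leading PC
    loadings = eigvec[:, 0].copy()
    anti_idx = [SCORE_COLUMNS.index(c) for c in ANTIOXIDANT_SCORES]
    if loadings[anti_idx].mean() < 0:
        loadings = -loadings
    score = pd.Series(z @ loadings, index=scores.index)
    weights = OBSWeights(
        "pca", pd.Series(loadings, index=SCORE_COLUMNS),
        provenance={"eigenvalues": eigval.tolist(),
                    "n_retained": retained})
    return OBSResult("pca", score, assign_quartiles(score), weights)


# ---------------------------------------------------------------------------
# quartiles
# ---------------------------------------------------------------------------

def assign_quartiles(score: pd.Series) -> pd.Series:
    """Cut a continuous score at its empirical 25/50/75 percentiles.

    Bins are lower-inclusive; Q1 holds the lowest scores (prooxidant
    predominance).  Adjacent cutpoints may coincide when the score is heavily
    tied (the affected bin is then empty), but a distribution whose 25th and
    75th percentiles coincide is rejected as degenerate.
    """
    arr = score.to_numpy(dtype=float)
    if len(np.unique(arr)) < 4:
        raise DegenerateDistributionError(
            "need at least 4 distinct score values for quartiles")
    cuts = np.quantile(arr, [0.25, 0.5, 0.75])
    if cuts[0] == cuts[2]:
        raise DegenerateDistributionError(
            "quartile cutpoints collapsed; score distribution is degenerate")
    idx = np.searchsorted(cuts, arr, side="left")
    labels = pd.Categorical.from_codes(idx, categories=QUARTILE_LABELS,
                                       ordered=True)
    return pd.Series(labels, index=score.index, name="quartile")


def _check_scores(scores: pd.DataFrame) -> None:
    missing = [c for c in SCORE_COLUMNS if c not in scores.columns]
    if missing:
        raise ValueError(f"score table lacks components: {missing}")
    allowed = {
        "alcohol_score": {0, 2},
    }
    for col in SCORE_COLUMNS:
        ok = allowed.get(col, {0, 1, 2})
        vals = set(pd.unique(scores[col]))
        if not vals.issubset(ok):
            raise ValueError(f"{col} takes values outside {sorted(ok)}: "
                             f"{sorted(vals - ok)}")


def score_cohort(cohort: pd.DataFrame, scheme: str, *,
                 outcome: pd.Series | None = None,
                 covariates: pd.DataFrame | None = None) -> OBSResult:
    """Convenience front end: cutpoints -> component scores -> weighting."""
    cuts = compute_all_cutpoints(cohort)
    scores = score_components(cohort, cuts)
    if scheme == "equal":
        return equal_weight_obs(scores)
    if scheme == "beta":
        if outcome is None or covariates is None:
            raise ValueError("beta weighting needs outcome and covariates")
        return beta_weight_obs(scores, covariates, outcome)
    if scheme == "pca":
        return pca_weight_obs(scores)
    raise ValueError(f"unknown weighting scheme {scheme!r}")
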