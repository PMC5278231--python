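"""Genome-wide per-SNP logistic interaction scan.

For every polymorphic SNP, fits

    logit P(MetS) = b0 + b_age Age + b_sex Sex + b_area Area
                    + b_obs OBS + b_bmi BMI + b_g G + b_gxobs G*OBS

where G is the additive minor-allele dosage and OBS the continuous
(beta-coefficient-weighted, standardized) oxidative balance score, and tests
H0: b_gxobs = 0 with a 1-df Wald test (likelihood-ratio mode optional).
SNP-level multiplicity is handled with Benjamini-Hochberg q-values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

COVARIATE_ORDER = ["age", "sex", "area", "bmi"]


@dataclass
class ScanResult:
    table: pd.DataFrame               # one row per tested SNP
    n_tested: int
    n_skipped: int
    obs_scheme: str
    skipped: list[str] = field(default_factory=list)


def code_genotypes(raw: pd.Series | np.ndarray) -> tuple[np.ndarray, float]:
    """Additive minor-allele dosage for one SNP.

    Input dosages count an arbitrary allele; if that allele's frequency
    exceeds 0.5 the coding is flipped (g -> 2 - g) so the returned vector
    counts the minor allele.  Missing values stay NaN (dropped per SNP by the
    caller).  Returns ``(dosage, maf)``.
    """
    g = np.asarray(raw, dtype=float)
    obs = g[~np.isnan(g)]
    if len(obs) == 0:
        return g, np.nan
    freq = obs.mean() / 2.0
    if freq > 0.5:
        g = 2.0 - g
        freq = 1.0 - freq
    return g, float(freq)


def fit_interaction(dosage: np.ndarray, obs_score: np.ndarray,
                    status: np.ndarray, covariates: pd.DataFrame, *,
                    test: str = "wald") -> dict:
    """Fit the per-SNP interaction model; returns a coefficient record.

    The record always carries every field; on separation or non-convergence
    ``converged`` is False and the p-value is NaN.
    """
    if test not in ("wald", "lrt"):
        raise ValueError("test must be 'wald' or 'lrt'")
    keep = ~np.isnan(dosage)
    g = dosage[keep]
    X = np.column_stack([
        np.ones(keep.sum()),
        covariates.loc[keep, COVARIATE_ORDER[:3]].to_numpy(dtype=float),
        obs_score[keep],
        covariates.loc[keep, "bmi"].to_numpy(dtype=float),
        g,
        g * obs_score[keep],
    ])
    y = status[keep].astype(float)
    names = ["const", "age", "sex", "area", "obs", "bmi", "g", "gxobs"]
    record = {f"beta_{nm}": np.nan for nm in names}
    record.update({"se_g": np.nan, "se_gxobs": np.nan, "p": np.nan,
                   "converged": False, "n": int(keep.sum())})
    try:
        fit = sm.Logit(y, X).fit(disp=0, maxiter=100)
    except Exception:
        return record
    if not fit.mle_retvals.get("converged", False):
        return record
    for i, nm in enumerate(names):
        record[f"beta_{nm}"] = float(fit.params[i])
    record["se_g"] = float(fit.bse[6])
    record["se_gxobs"] = float(fit.bse[7])
    record["converged"] = True
    if test == "wald":
        record["p"] = float(fit.pvalues[7])
    else:
        null = sm.Logit(y, X[:, :7]).fit(disp=0, maxiter=100)
        lr = 2.0 * (fit.llf - null.llf)
        record["p"] = float(stats.chi2.sf(max(lr, 0.0), df=1))
    return record


def scan_genome(dosage: pd.DataFrame, obs_score: pd.Series,
                status: pd.Series, covariates: pd.DataFrame, *,
                test: str = "wald", standardize_obs: bool = True,
                chunk_size: int | None = None,
                snp_info: pd.DataFrame | None = None) -> ScanResult:
    """One interaction fit per polymorphic SNP, in deterministic input order.

    Participant indices of all inputs must agree exactly.  Monomorphic SNPs
    are skipped with a log entry.  ``chunk_size`` only controls the work
    batching (results are identical chunked or not).
    """
    for other, name in ((obs_score, "obs_score"), (status, "status"),
                        (covariates, "covariates")):
        if not dosage.index.equals(other.index):
            raise ValueError(f"participant ids of dosage and {name} differ")

    obs_arr = obs_score.to_numpy(dtype=float)
    if standardize_obs:
        obs_arr = (obs_arr - obs_arr.mean()) / obs_arr.std(ddof=0)
    y = status.to_numpy(dtype=int)

    pos_lookup = None
    if snp_info is not None:
        pos_lookup = snp_info.set_index("snp")[["chrom", "pos"]]

    snps = list(dosage.columns)
    chunk = chunk_size or len(snps)
    rows, skipped = [], []
    for start in range(0, len(snps), max(chunk, 1)):
        for snp in snps[start:start + chunk]:
            g, maf = code_genotypes(dosage[snp])
            valid = g[~np.isnan(g)]
            if len(np.unique(valid)) < 2:
                skipped.append(snp)
                logger.info("scan: skipping monomorphic SNP %s", snp)
                continue
            rec = fit_interaction(g, obs_arr, y, covariates, test=test)
            rec["snp"] = snp
            rec["maf"] = maf
            if pos_lookup is not None and snp in pos_lookup.index:
                rec["chrom"] = pos_lookup.loc[snp, "chrom"]
                rec["pos"] = int(pos_lookup.loc[snp, "pos"])
            rows.append(rec)
    table = pd.DataFrame(rows)
    if len(table):
        table["q"] = np.nan
        ok = table["p"].notna()
        if ok.any():
            table.loc[ok, "q"] = bh_qvalues(table.loc[ok, "p"].to_numpy())
        front = [c for c in ("snp", "chrom", "pos", "maf") if c in table]
        table = table[front + [c for c in table.columns if c not in front]]
    return ScanResult(table=table, n_tested=len(rows),
                      n_skipped=len(skipped), obs_scheme="beta",
                      skipped=skipped)


def bh_qvalues(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone by construction)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p <= 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q
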