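"""Synthetic cohort, genotype, annotation, and outcome generator.

Every downstream stage of the pipeline (scoring, phenotype classification,
association models, the genome-wide interaction scan, pathway enrichment) is
exercised on data from this module, which emulates a middle-aged
population-based cohort: skewed (log-normal) nutrient intakes, sex-dependent
smoking, zero-inflated alcohol, biallelic SNPs in Hardy-Weinberg proportions,
non-overlapping gene intervals with pathway gene sets, and planted
SNP-by-oxidative-balance interaction effects concentrated in designated
pathways.

Two outcome generators are provided:

* :func:`generate_outcomes` — a liability-threshold model for the five
  metabolic-syndrome component traits, emitting continuous measurements
  (waist, lipids, blood pressures, glucose) consistent with the intended
  binary states plus inflammation markers, so phenotype classification can
  be validated against ground truth.
* :func:`generate_case_control` — a binary outcome drawn from the exact
  per-SNP logistic interaction model.  Calibration and coefficient-recovery
  studies use this path: thresholding five liabilities and requiring three
  adverse components attenuates coefficients, so only the direct logistic
  outcome carries the planted log-odds at face value.

All generators are bit-reproducible: every random stream is derived from
``config.seed`` plus a fixed per-stage offset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from . import obs as obs_mod
from .io_formats import GeneSet

FLANK_BP = 100_000

# random-stream offsets, one per generator stage
_STREAM_COHORT = 1
_STREAM_GENES = 2
_STREAM_PATHWAYS = 3
_STREAM_GENOTYPES = 4
_STREAM_OUTCOMES = 5
_STREAM_CASECONTROL = 6

# per-component liability coefficients on (age_std, sex, bmi_std); the five
# components are ordered as in mets.COMPONENT_COLUMNS
_LIABILITY_COEFS = np.array([
    #  age   sex   bmi
    [0.10, 0.10, 0.80],   # abdominal obesity
    [0.10, -0.15, 0.35],  # hypertriglyceridemia
    [0.05, 0.30, 0.20],   # low HDL
    [0.35, -0.05, 0.25],  # high blood pressure
    [0.30, -0.10, 0.25],  # high fasting glucose
])

COMPONENT_ORDER = ["abdominal_obesity", "hypertriglyceridemia", "low_hdl",
                   "high_blood_pressure", "high_fasting_glucose"]


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic study; defaults define the study conditions."""

    n_participants: int = 2000
    n_snps: int = 900
    n_genes: int = 240
    n_pathways: int = 50
    pathway_size_range: tuple[int, int] = (25, 40)
    maf_range: tuple[float, float] = (0.05, 0.5)
    causal_pathway_ids: tuple[str, ...] = ("PW000",)
    n_causal_snps_per_pathway: int = 10
    interaction_beta: float = 0.5     # log-odds per dosage x standardized-OBS
    obs_main_beta: float = -0.3       # log-odds per standardized-OBS unit
    snp_main_beta: float = 0.1        # log-odds per dosage at causal SNPs
    component_prevalences: tuple[float, ...] = (0.34, 0.31, 0.56, 0.21, 0.19)
    marker_obs_slopes: tuple[float, float] = (-0.10, -0.35)  # CRP(log), WBC
    noise_sd: float = 1.0
    snp_placement: tuple[float, float, float] = (0.6, 0.25, 0.15)
    missingness: float = 0.0
    treated_fraction: float = 0.3     # of adverse BP/glucose cases medicated
    seed: int = 2017

    def __post_init__(self) -> None:
        if self.n_participants <= 0:
            raise ValueError("n_participants must be positive")
        for name in ("n_snps", "n_genes", "n_pathways"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        plo, phi = self.pathway_size_range
        if not (20 <= plo <= phi <= 200):
            raise ValueError("pathway_size_range must lie within the "
                             "enrichment size filter bounds [20, 200]")
        if phi > self.n_genes:
            raise ValueError("n_genes too small for pathway_size_range")
        if len(self.component_prevalences) != 5:
            raise ValueError("need 5 component prevalences")
        if not all(0 < p < 1 for p in self.component_prevalences):
            raise ValueError("component prevalences must lie in (0, 1)")
        if not np.isclose(sum(self.snp_placement), 1.0):
            raise ValueError("snp_placement fractions must sum to 1")
        if not 0 <= self.missingness < 1:
            raise ValueError("missingness must lie in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


@dataclass(frozen=True)
class GroundTruth:
    """Planted-effect records for validating recovery downstream."""

    causal_snp_ids: tuple[str, ...]
    interaction_betas: dict[str, float]      # per causal SNP
    snp_main_betas: dict[str, float]
    liability_coefs: pd.DataFrame            # component x (age, sex, bmi)
    obs_main_beta: float
    marker_slopes: tuple[float, float]
    causal_pathway_ids: tuple[str, ...]


@dataclass
class SimulatedStudy:
    cohort: pd.DataFrame
    dosage: pd.DataFrame
    snp_info: pd.DataFrame
    genes: pd.DataFrame
    pathways: list[GeneSet]
    truth: GroundTruth
    config: SimulationConfig


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def generate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Generate the baseline exposure/covariate table.

    Age is uniform on 40-75 years; nutrient intakes are log-normal (right
    skewed, as food-frequency-questionnaire intakes are); alcohol is
    zero-inflated log-normal; physical activity is normal truncated at zero;
    smoking prevalence is sex-dependent.  Medication flags are initialized to
    zero and set by :func:`generate_outcomes`.
    """
    rng = _rng(config, _STREAM_COHORT)
    n = config.n_participants

    sex = rng.integers(0, 2, n)                      # 1 = female
    cohort = pd.DataFrame({
        "pid": [f"P{i:06d}" for i in range(n)],
        "age": rng.uniform(40, 75, n).round(1),
        "sex": sex,
        "area": rng.integers(0, 2, n),               # 1 = urban
        "bmi": rng.normal(24.5, 3.0, n).round(2),
        "vitamin_c": rng.lognormal(np.log(90), 0.55, n),
        "retinol": rng.lognormal(np.log(45), 0.80, n),
        "carotene": rng.lognormal(np.log(1800), 0.80, n),
        "iron": rng.lognormal(np.log(9), 0.45, n),
        "total_energy": rng.lognormal(np.log(1750), 0.30, n),
    })

    # smoking: Korean-cohort-like pattern, males smoke far more
    male_p = np.array([0.35, 0.30, 0.35])            # never/former/current
    female_p = np.array([0.90, 0.04, 0.06])
    levels = np.array(["never", "former", "current"])
    draws = np.empty(n, dtype=object)
    u = rng.random(n)
    for s, probs in ((0, male_p), (1, female_p)):
        mask = sex == s
        draws[mask] = levels[np.searchsorted(np.cumsum(probs), u[mask])]
    cohort["smoking"] = draws

    drinks = rng.random(n) < np.where(sex == 1, 0.25, 0.75)
    amount = rng.lognormal(np.log(12), 1.0, n)
    cohort["alcohol_g_day"] = np.where(drinks, amount, 0.0)

    activity = rng.normal(82, 21, n)
    cohort["activity_met_day"] = np.clip(activity, 0.0, None)

    for col in ("antihypertensive_med", "antidiabetic_med", "insulin_med"):
        cohort[col] = 0

    if config.missingness > 0:
        for col in ("vitamin_c", "retinol", "carotene", "iron",
                    "activity_met_day"):
            mask = rng.random(n) < config.missingness
            cohort.loc[mask, col] = np.nan

    return cohort.set_index("pid", drop=False)


# ---------------------------------------------------------------------------
# annotation: genes and pathways
# ---------------------------------------------------------------------------

_GENES_PER_CHROM = 60
_GENE_SPACING = 250_000
_GENE_MIN_LEN, _GENE_MAX_LEN = 5_000, 30_000


def _gene_layout(config: SimulationConfig) -> pd.DataFrame:
    """Non-overlapping gene intervals (1-based inclusive), deterministic."""
    rng = _rng(config, _STREAM_GENES)
    rows = []
    for i in range(config.n_genes):
        chrom = f"chr{i // _GENES_PER_CHROM + 1}"
        slot = i % _GENES_PER_CHROM
        start = 1 + slot * _GENE_SPACING
        length = int(rng.integers(_GENE_MIN_LEN, _GENE_MAX_LEN + 1))
        rows.append((f"G{i:04d}", chrom, start, start + length - 1))
    return pd.DataFrame(rows, columns=["gene", "chrom", "start", "end"])


def _build_pathways(config: SimulationConfig,
                    genes: pd.DataFrame) -> list[GeneSet]:
    rng = _rng(config, _STREAM_PATHWAYS)
    ids = [f"PW{i:03d}" for i in range(config.n_pathways)]
    unknown = set(config.causal_pathway_ids) - set(ids)
    if unknown:
        raise ValueError(f"causal_pathway_ids not among generated pathway "
                         f"ids: {sorted(unknown)}")
    gene_ids = genes["gene"].to_numpy()
    lo, hi = config.pathway_size_range
    sets = []
    for pid in ids:
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(gene_ids, size=size, replace=False)
        desc = ("planted interaction pathway" if pid in
                config.causal_pathway_ids else "background pathway")
        sets.append(GeneSet(pid, desc, tuple(sorted(members))))
    return sets


def generate_annotation(config: SimulationConfig
                        ) -> tuple[pd.DataFrame, list[GeneSet]]:
    """Gene intervals plus pathway gene sets with sizes in the configured
    range.  Causal pathways contain the genes that will host causal SNPs."""
    genes = _gene_layout(config)
    return genes, _build_pathways(config, genes)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def _place_snps(config: SimulationConfig, genes: pd.DataFrame,
                causal_genes_per_pathway: dict[str, np.ndarray],
                rng: np.random.Generator) -> pd.DataFrame:
    """SNP map: configured fractions inside genes / within the 100 kb flank /
    in the far band; causal SNPs forced inside causal-pathway genes."""
    n = config.n_snps
    f_in, f_near, _ = config.snp_placement
    n_in = int(round(n * f_in))
    n_near = int(round(n * f_near))
    categories = np.array(["in"] * n_in + ["near"] * n_near
                          + ["far"] * (n - n_in - n_near))

    gene_arr = genes.reset_index(drop=True)
    rows = []
    causal_ids: list[str] = []
    causal_iter = [(pid, g) for pid, garr in causal_genes_per_pathway.items()
                   for g in garr]
    for j in range(n):
        snp = f"rs{j:06d}"
        cat = categories[j]
        if j < len(causal_iter):
            # plant causal SNPs inside their pathway's genes, round-robin
            _, gene_name = causal_iter[j]
            g = gene_arr[gene_arr["gene"] == gene_name].iloc[0]
            pos = int(rng.integers(g["start"], g["end"] + 1))
            causal_ids.append(snp)
        else:
            g = gene_arr.iloc[int(rng.integers(len(gene_arr)))]
            if cat == "in":
                pos = int(rng.integers(g["start"], g["end"] + 1))
            elif cat == "near":
                off = int(rng.integers(1, FLANK_BP + 1))
                pos = (g["end"] + off if rng.random() < 0.5
                       else max(1, g["start"] - off))
            else:
                # beyond the flank of this gene but short of the next one's
                pos = int(g["end"] + FLANK_BP + 1
                          + rng.integers(0, 40_000))
        rows.append((snp, g["chrom"], pos))

    info = pd.DataFrame(rows, columns=["snp", "chrom", "pos"])
    alleles = np.array(["A", "C", "G", "T"])
    a1 = rng.integers(0, 4, n)
    a2 = (a1 + 1 + rng.integers(0, 3, n)) % 4
    info["a1"] = alleles[a1]
    info["a2"] = alleles[a2]
    info["causal"] = info["snp"].isin(causal_ids)
    return info


def _causal_gene_assignment(config: SimulationConfig,
                            pathways: Sequence[GeneSet]
                            ) -> dict[str, np.ndarray]:
    by_id = {p.name: p for p in pathways}
    out = {}
    for pid in config.causal_pathway_ids:
        members = np.asarray(by_id[pid].genes)
        k = config.n_causal_snps_per_pathway
        # round-robin over the pathway's genes so several genes host effects
        out[pid] = members[np.arange(k) % len(members)]
    return out


def generate_genotypes(config: SimulationConfig
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Additive dosage matrix (participants x SNPs, values 0/1/2) and SNP map.

    Each SNP's minor-allele frequency is uniform on ``maf_range``; genotypes
    are binomial(2, maf), i.e. Hardy-Weinberg proportions with independent
    SNPs (no linkage disequilibrium).
    """
    genes, pathways = generate_annotation(config)
    causal = _causal_gene_assignment(config, pathways)
    return _generate_genotypes_impl(config, genes, causal)


def _generate_genotypes_impl(config: SimulationConfig, genes: pd.DataFrame,
                             causal_genes: dict[str, np.ndarray]
                             ) -> tuple[pd.DataFrame, pd.DataFrame]:
    rng = _rng(config, _STREAM_GENOTYPES)
    info = _place_snps(config, genes, causal_genes, rng)
    lo, hi = config.maf_range
    maf = rng.uniform(lo, hi, config.n_snps)
    info["maf"] = maf
    geno = rng.binomial(2, maf, size=(config.n_participants, config.n_snps))
    pids = [f"P{i:06d}" for i in range(config.n_participants)]
    dosage = pd.DataFrame(geno, index=pd.Index(pids, name="pid"),
                          columns=info["snp"].to_numpy())
    return dosage, info


# ---------------------------------------------------------------------------
# outcomes
# ---------------------------------------------------------------------------

def true_antioxidant_index(cohort: pd.DataFrame) -> pd.Series:
    """The standardized equal-weight OBS of the generated exposures.

    This is the index effects are planted on: the simplest scheme, so the
    ground truth stays independent of any fitted weights downstream.
    """
    cuts = obs_mod.compute_all_cutpoints(cohort)
    scores = obs_mod.score_components(cohort, cuts)
    total = scores.sum(axis=1).astype(float)
    return (total - total.mean()) / total.std(ddof=0)


def build_truth(config: SimulationConfig, snp_info: pd.DataFrame
                ) -> GroundTruth:
    causal_ids = tuple(snp_info.loc[snp_info["causal"], "snp"])
    return GroundTruth(
        causal_snp_ids=causal_ids,
        interaction_betas={s: config.interaction_beta for s in causal_ids},
        snp_main_betas={s: config.snp_main_beta for s in causal_ids},
        liability_coefs=pd.DataFrame(_LIABILITY_COEFS,
                                     index=COMPONENT_ORDER,
                                     columns=["age", "sex", "bmi"]),
        obs_main_beta=config.obs_main_beta,
        marker_slopes=config.marker_obs_slopes,
        causal_pathway_ids=tuple(config.causal_pathway_ids),
    )


def _liabilities(cohort: pd.DataFrame, dosage: pd.DataFrame,
                 truth: GroundTruth, config: SimulationConfig,
                 rng: np.random.Generator) -> tuple[np.ndarray, pd.Series]:
    n = len(cohort)
    z = true_antioxidant_index(cohort).to_numpy()
    age_std = (cohort["age"] - cohort["age"].mean()).to_numpy() / cohort["age"].std(ddof=0)
    bmi_std = (cohort["bmi"] - cohort["bmi"].mean()).to_numpy() / cohort["bmi"].std(ddof=0)
    sexv = cohort["sex"].to_numpy(dtype=float)
    covs = np.column_stack([age_std, sexv, bmi_std])

    # dosages enter centered: g z = (g - mu) z + mu z, so each SNP's
    # interaction coefficient stays interaction_beta while the aggregate of
    # many planted SNPs does not inflate the marginal OBS effect
    g_term = np.zeros(n)
    gz_term = np.zeros(n)
    for snp in truth.causal_snp_ids:
        g = dosage[snp].to_numpy(dtype=float)
        gc = g - g.mean()
        g_term += truth.snp_main_betas[snp] * gc
        gz_term += truth.interaction_betas[snp] * gc * z

    liab = np.empty((n, 5))
    for c in range(5):
        eps = rng.normal(0.0, config.noise_sd, n)
        liab[:, c] = (covs @ _LIABILITY_COEFS[c] + truth.obs_main_beta * z
                      + g_term + gz_term + eps)
    return liab, pd.Series(z, index=cohort.index, name="true_index")


def generate_outcomes(cohort: pd.DataFrame, dosage: pd.DataFrame,
                      truth: GroundTruth,
                      config: SimulationConfig) -> pd.DataFrame:
    """Augment the cohort with MetS component traits and inflammation markers.

    Each component has a latent liability (covariates + planted OBS, SNP and
    SNPxOBS effects + noise) thresholded at the empirical quantile matching
    its configured prevalence; the continuous measurement is then placed on
    the adverse side of the clinical cut-off exactly when the liability is,
    so phenotype classification reproduces the intended state.  A fraction of
    adverse blood-pressure/glucose cases instead carry a medication flag with
    a controlled (sub-threshold) measurement.
    """
    if not cohort.index.equals(dosage.index):
        raise ValueError("cohort and dosage tables are not row-aligned")
    rng = _rng(config, _STREAM_OUTCOMES)
    out = cohort.copy()
    liab, z = _liabilities(cohort, dosage, truth, config, rng)
    n = len(out)
    female = out["sex"].to_numpy() == 1

    thresholds = [np.quantile(liab[:, c], 1 - config.component_prevalences[c])
                  for c in range(5)]
    delta = [liab[:, c] - thresholds[c] for c in range(5)]

    # abdominal obesity: waist >= 90 (men) / 85 (women)
    waist_cut = np.where(female, 85.0, 90.0)
    out["waist"] = waist_cut + 8.0 * delta[0]
    # hypertriglyceridemia: TG >= 150
    out["triglycerides"] = np.clip(150.0 + 45.0 * delta[1], 20.0, None)
    # low HDL: < 40 (men) / < 50 (women); adverse side is strictly below
    hdl_cut = np.where(female, 50.0, 40.0)
    out["hdl"] = np.clip(hdl_cut - 9.0 * delta[2], 5.0, None)

    # blood pressure: sbp >= 130 or dbp >= 85 or medication
    adverse_bp = delta[3] >= 0
    treated_bp = adverse_bp & (rng.random(n) < config.treated_fraction)
    sbp = 130.0 + 7.0 * delta[3]
    sbp[treated_bp] = 118.0 + rng.uniform(-8, 8, treated_bp.sum())
    out["sbp"] = sbp
    out["dbp"] = np.clip(78.0 + 2.0 * np.minimum(delta[3], 0.0)
                         + rng.normal(0, 2, n), 40.0, 84.0)
    out["antihypertensive_med"] = treated_bp.astype(int)

    # fasting glucose: >= 100 or medication
    adverse_glu = delta[4] >= 0
    treated_glu = adverse_glu & (rng.random(n) < config.treated_fraction)
    glu = 100.0 + 11.0 * delta[4]
    glu[treated_glu] = 90.0 + rng.uniform(-6, 8, treated_glu.sum())
    out["fasting_glucose"] = glu
    out["antidiabetic_med"] = treated_glu.astype(int)
    out["insulin_med"] = (treated_glu
                          & (rng.random(n) < 0.25)).astype(int)

    # supporting diabetes labs, correlated with the glucose liability
    out["hba1c"] = np.clip(5.5 + 0.35 * delta[4] + rng.normal(0, 0.15, n),
                           4.0, None).round(2)
    out["ogtt_2h"] = np.clip(120.0 + 25.0 * delta[4] + rng.normal(0, 10, n),
                             50.0, None).round(0)

    crp_slope, wbc_slope = config.marker_obs_slopes
    out["crp"] = np.exp(-0.5 + crp_slope * z.to_numpy()
                        + rng.normal(0, 0.8, n)).round(3)
    out["wbc"] = np.clip(6.4 + wbc_slope * z.to_numpy()
                         + rng.normal(0, 1.6, n), 1.0, None).round(2)

    # intended component states, for round-trip checks against classification
    for c, name in enumerate(COMPONENT_ORDER):
        if name == "low_hdl":
            state = delta[c] > 0   # '<' criterion: adverse strictly below
        else:
            state = delta[c] >= 0
        out[f"true_{name}"] = state.astype(int)
    out["true_mets"] = (out[[f"true_{c}" for c in COMPONENT_ORDER]]
                        .sum(axis=1) >= 3).astype(int)
    return out


def generate_case_control(cohort: pd.DataFrame, dosage: pd.DataFrame,
                          truth: GroundTruth, config: SimulationConfig, *,
                          base_prevalence: float = 0.25) -> pd.Series:
    """Binary outcome from the exact logistic interaction model.

    logit P(y=1) = b0 + 0.02 age_c + 0.3 sex_c + 0.1 area_c + b_obs z
                   + 0.05 bmi_c + sum_j [b_g g_j + b_gxobs g_j z]

    with z the standardized true antioxidant index, every covariate centered,
    and b0 = logit(``base_prevalence``), so the marginal prevalence sits near
    the target.
    """
    if not cohort.index.equals(dosage.index):
        raise ValueError("cohort and dosage tables are not row-aligned")
    rng = _rng(config, _STREAM_CASECONTROL)
    z = true_antioxidant_index(cohort).to_numpy()
    age_c = cohort["age"].to_numpy() - cohort["age"].mean()
    bmi_c = cohort["bmi"].to_numpy() - cohort["bmi"].mean()
    sex_c = cohort["sex"].to_numpy() - cohort["sex"].mean()
    area_c = cohort["area"].to_numpy() - cohort["area"].mean()
    eta = (np.log(base_prevalence / (1 - base_prevalence))
           + 0.02 * age_c + 0.3 * sex_c + 0.1 * area_c
           + truth.obs_main_beta * z + 0.05 * bmi_c)
    for snp in truth.causal_snp_ids:
        g = dosage[snp].to_numpy(dtype=float)
        gc = g - g.mean()       # centered; see _liabilities
        eta += truth.snp_main_betas[snp] * gc
        eta += truth.interaction_betas[snp] * gc * z
    p = 1.0 / (1.0 + np.exp(-eta))
    y = rng.binomial(1, p)
    return pd.Series(y, index=cohort.index, name="status")


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def simulate_study(config: SimulationConfig = SimulationConfig()
                   ) -> SimulatedStudy:
    """Run the full generator chain and return every artifact."""
    genes, pathways = generate_annotation(config)
    causal_genes = _causal_gene_assignment(config, pathways)
    dosage, snp_info = _generate_genotypes_impl(config, genes, causal_genes)
    cohort = generate_cohort(config)
    truth = build_truth(config, snp_info)
    cohort = generate_outcomes(cohort, dosage, truth, config)
    return SimulatedStudy(cohort, dosage, snp_info, genes, pathways, truth,
                          config)


def write_study(study: SimulatedStudy, outdir) -> None:
    """Write every artifact of a simulated study under ``outdir``."""
    from pathlib import Path
    from . import io_formats as iof

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = {"seed": study.config.seed}
    iof.write_phenotypes(study.cohort.reset_index(drop=True),
                         outdir / "phenotypes.tsv", params=params)
    iof.write_dosage_tsv(study.dosage, study.snp_info,
                         outdir / "genotypes", params=params)
    iof.write_bed(study.genes, outdir / "genes.bed")
    iof.write_gmt(study.pathways, outdir / "pathways.gmt")
    truth_df = pd.DataFrame({
        "snp": list(study.truth.causal_snp_ids),
        "interaction_beta": [study.truth.interaction_betas[s]
                             for s in study.truth.causal_snp_ids],
        "main_beta": [study.truth.snp_main_betas[s]
                      for s in study.truth.causal_snp_ids],
    })
    iof.write_table(truth_df, outdir / "truth.tsv", params=params)
    cfg = asdict(study.config)
    iof.write_config(cfg, outdir / "config.yaml")
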