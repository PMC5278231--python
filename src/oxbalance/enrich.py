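"""Pathway-level enrichment of SNP interaction p-values.

A significance-proportion-corrected gene-set enrichment analysis in the
i-GSEA style, reconstructed for G x environment scan output:

1. SNPs are mapped to genes with a +/-100 kb flank (inclusive).
2. Each gene's statistic is the max of -log10 p over its mapped SNPs; genes
   are ranked descending (ties broken lexicographically by gene id).
3. Gene sets are size-filtered (20-200 genes by default, counted over the
   *selected* genes, i.e. those present in the ranking).
4. The enrichment score ES is the signed maximum deviation of a weighted
   Kolmogorov-Smirnov running sum: increments |statistic|^w at set genes
   (normalized by their total), decrements 1/(N - N_set) elsewhere.
5. A gene is "significant" when at least one of its SNPs falls in the top
   fraction (default 5%) of all SNP p-values; the correction factor
   k = (significant proportion within the set) / (significant proportion
   among all selected genes), and ES* = k * ES.
6. SNP-label permutation: p-values are reassigned to SNP positions B times
   and every quantity is recomputed, giving nominal pathway p-values and a
   GSEA-style permutation FDR (a Benjamini-Hochberg FDR over the nominal
   p-values is reported alongside).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import GeneSet
from .scan import bh_qvalues

logger = logging.getLogger(__name__)

DEFAULT_FLANK = 100_000


@dataclass(frozen=True)
class EnrichmentConfig:
    min_genes: int = 20
    max_genes: int = 200
    top_fraction: float = 0.05
    permutations: int = 1000
    weight_exponent: float = 1.0
    seed: int = 0
    fdr_threshold: float = 0.05
    filter_on: str = "selected"       # or "all"
    flank: int = DEFAULT_FLANK

    def __post_init__(self) -> None:
        if not 0 < self.top_fraction < 1:
            raise ValueError("top_fraction must lie in (0, 1)")
        if self.permutations < 100:
            raise ValueError("need at least 100 permutations")
        if self.filter_on not in ("selected", "all"):
            raise ValueError("filter_on must be 'selected' or 'all'")
        if self.min_genes < 1 or self.max_genes < self.min_genes:
            raise ValueError("invalid gene-set size filter")


# ---------------------------------------------------------------------------
# SNP -> gene mapping
# ---------------------------------------------------------------------------

def map_snps_to_genes(snp_info: pd.DataFrame, genes: pd.DataFrame,
                      flank: int = DEFAULT_FLANK) -> pd.DataFrame:
    """Map SNPs to genes within ``[start - flank, end + flank]`` (inclusive).

    ``snp_info`` carries 1-based positions (snp, chrom, pos); ``genes``
    carries 1-based inclusive intervals (gene, chrom, start, end).  A SNP may
    map to several genes.  SNPs on chromosomes absent from the gene table are
    logged and left unmapped.  Returns one row per gene: gene, chrom, start,
    end, snps (tuple of mapped SNP ids, possibly empty).
    """
    known = set(genes["chrom"])
    stray = set(snp_info["chrom"]) - known
    if stray:
        n = int(snp_info["chrom"].isin(stray).sum())
        logger.warning("map_snps_to_genes: %d SNPs on chromosomes %s have "
                       "no genes and stay unmapped", n, sorted(stray))
    mapped: dict[str, list[str]] = {g: [] for g in genes["gene"]}
    for chrom, gsub in genes.groupby("chrom", sort=False):
        ssub = snp_info[snp_info["chrom"] == chrom]
        if ssub.empty:
            continue
        pos = ssub["pos"].to_numpy(dtype=np.int64)
        lo = gsub["start"].to_numpy(dtype=np.int64) - flank
        hi = gsub["end"].to_numpy(dtype=np.int64) + flank
        hit = (pos[None, :] >= lo[:, None]) & (pos[None, :] <= hi[:, None])
        snp_ids = ssub["snp"].to_numpy()
        for gi, gname in enumerate(gsub["gene"]):
            mapped[gname] = snp_ids[hit[gi]].tolist()
    out = genes.copy()
    out["snps"] = out["gene"].map(lambda g: tuple(mapped[g]))
    return out


# ---------------------------------------------------------------------------
# gene statistics and significance
# ---------------------------------------------------------------------------

class _GeneIndex:
    """Flat SNP-index arrays per gene for fast recomputation under
    permutation (np.maximum.reduceat over a shared -log10 p vector)."""

    def __init__(self, pvals: pd.Series, gene_map: pd.DataFrame):
        snp_pos = {s: i for i, s in enumerate(pvals.index)}
        genes, flat, offsets = [], [], []
        for gname, snps in zip(gene_map["gene"], gene_map["snps"]):
            idx = [snp_pos[s] for s in snps if s in snp_pos]
            if not idx:
                continue        # untested gene: not "selected"
            genes.append(gname)
            offsets.append(len(flat))
            flat.extend(idx)
        order = np.argsort(np.asarray(genes))       # lexicographic gene order
        # rebuild flat arrays in sorted-gene order
        genes_arr = np.asarray(genes)[order]
        lengths = np.diff(offsets + [len(flat)])
        flat_arr = np.asarray(flat, dtype=np.intp)
        new_flat, new_off = [], []
        for gi in order:
            new_off.append(len(new_flat))
            start = offsets[gi]
            new_flat.extend(flat_arr[start:start + lengths[gi]])
        self.genes = genes_arr
        self.flat = np.asarray(new_flat, dtype=np.intp)
        self.offsets = np.asarray(new_off, dtype=np.intp)
        self.neglogp = -np.log10(pvals.to_numpy(dtype=float))
        self.n_snps = len(pvals)

    def stats(self, neglog: np.ndarray) -> np.ndarray:
        return np.maximum.reduceat(neglog[self.flat], self.offsets)

    def significant(self, sig_snp: np.ndarray) -> np.ndarray:
        return np.maximum.reduceat(sig_snp[self.flat].astype(np.int8),
                                   self.offsets).astype(bool)


def gene_statistics(pvals: pd.Series, gene_map: pd.DataFrame) -> pd.DataFrame:
    """Ranked gene list: statistic = max -log10 p over mapped SNPs.

    Genes with no tested SNPs are dropped.  Sorted by descending statistic,
    ties broken lexicographically by gene id (determinism).
    """
    index = _GeneIndex(pvals, gene_map)
    stats = index.stats(index.neglogp)
    df = pd.DataFrame({"gene": index.genes, "stat": stats})
    df = df.sort_values(["stat", "gene"], ascending=[False, True],
                        kind="mergesort").reset_index(drop=True)
    return df


def filter_gene_sets(sets: Sequence[GeneSet], ranked_genes: pd.DataFrame,
                     config: EnrichmentConfig = EnrichmentConfig()
                     ) -> list[GeneSet]:
    """Apply the 20-200 size filter.

    By default the filter counts *selected* genes (members present in the
    ranked list); ``filter_on='all'`` counts the full annotated membership.
    """
    present = set(ranked_genes["gene"])
    eligible = []
    for gs in sets:
        count = (len(gs.genes) if config.filter_on == "all"
                 else sum(g in present for g in gs.genes))
        if config.min_genes <= count <= config.max_genes:
            eligible.append(gs)
        else:
            logger.info("filter_gene_sets: excluding %s (size %d)",
                        gs.name, count)
    if not eligible:
        raise ValueError("no gene set survives the size filter")
    return eligible


def enrichment_score(ranked_genes: pd.DataFrame, set_genes: Sequence[str],
                     weight_exponent: float = 1.0) -> float:
    """Weighted Kolmogorov-Smirnov enrichment score.

    Walking down the ranking, the running sum gains
    ``|stat|^w / sum_set |stat|^w`` at set members and loses
    ``1 / (N - N_set)`` elsewhere; ES is the signed maximum deviation.
    """
    members = set(set_genes) & set(ranked_genes["gene"])
    if not members:
        raise ValueError("gene set has no overlap with the ranked list")
    mask = ranked_genes["gene"].isin(members).to_numpy()
    stats = ranked_genes["stat"].to_numpy(dtype=float)
    n, m = len(stats), int(mask.sum())
    if n == m:
        raise ValueError("gene set covers the whole ranking; ES undefined")
    w = np.abs(stats) ** weight_exponent
    denom = w[mask].sum()
    hit = (mask * w / denom) if denom > 0 else mask / m
    running = np.cumsum(hit - (~mask) / (n - m))
    return float(running[np.argmax(np.abs(running))])


def snp_significance_threshold(pvals: pd.Series | np.ndarray,
                               top_fraction: float) -> float:
    """The p-value cut below-or-at which a SNP counts as top-fraction."""
    return float(np.quantile(np.asarray(pvals, dtype=float), top_fraction))


def significance_proportion(set_genes: Sequence[str],
                            ranked_genes: pd.DataFrame,
                            significant_genes: Sequence[str]) -> float:
    """Correction factor k = (sig. proportion in set) / (overall sig.
    proportion among selected genes).  Returns 0 when the set has no
    significant member; raises when no gene at all is significant (k is then
    undefined and the pathway p-value is set to 1 by the caller)."""
    selected = list(ranked_genes["gene"])
    sig = set(significant_genes)
    overall = sum(g in sig for g in selected) / len(selected)
    if overall == 0:
        raise ZeroDivisionError("no significant genes among selected genes")
    members = [g for g in set_genes if g in set(selected)]
    in_set = sum(g in sig for g in members) / len(members)
    return in_set / overall


# ---------------------------------------------------------------------------
# permutation engine
# ---------------------------------------------------------------------------

def _corrected_scores(index: _GeneIndex, neglog: np.ndarray,
                      sig_snp: np.ndarray, member: np.ndarray,
                      set_sizes: np.ndarray,
                      weight_exponent: float) -> np.ndarray:
    """ES* = k * ES for every pathway under one assignment of p-values.

    ``member`` is a pathways x genes boolean matrix in ``index.genes`` order.
    """
    stats = index.stats(neglog)
    n_genes = len(stats)
    order = np.lexsort((np.arange(n_genes), -stats))
    mask = member[:, order]
    w = np.abs(stats[order]) ** weight_exponent

    hitw = mask * w
    denom = hitw.sum(axis=1)
    flat = denom == 0
    if flat.any():             # all-zero statistics in the set: unweighted
        hitw[flat] = mask[flat]
        denom[flat] = set_sizes[flat]
    miss = (~mask) / (n_genes - set_sizes)[:, None]
    running = np.cumsum(hitw / denom[:, None] - miss, axis=1)
    es = running[np.arange(len(running)),
                 np.argmax(np.abs(running), axis=1)]

    sig_gene = index.significant(sig_snp)
    overall = sig_gene.mean()
    if overall == 0:
        return np.zeros_like(es)
    # float cast: a boolean matmul would compute logical-any, not a count
    k = (member.astype(float) @ sig_gene.astype(float)) / set_sizes / overall
    return k * es


def permutation_fdr(pvals: pd.Series, gene_map: pd.DataFrame,
                    sets: Sequence[GeneSet],
                    config: EnrichmentConfig = EnrichmentConfig()
                    ) -> pd.DataFrame:
    """Permutation-based enrichment over all eligible gene sets.

    SNP p-values are reassigned to SNP positions ``config.permutations``
    times; gene statistics, ES, k and ES* are recomputed each time.  The
    nominal pathway p is ``(1 + #{ES*_perm >= ES*_obs}) / (B + 1)``; the
    permutation FDR follows the GSEA recipe on pathway-normalized ES*
    (fraction of pooled permuted values at or above the observed, divided by
    the corresponding observed fraction, clipped to [0, 1]).  A BH FDR over
    the nominal p-values is reported alongside as ``fdr_bh``.
    """
    index = _GeneIndex(pvals, gene_map)
    ranked = gene_statistics(pvals, gene_map)
    eligible = filter_gene_sets(sets, ranked, config)

    gene_pos = {g: i for i, g in enumerate(index.genes)}
    member = np.zeros((len(eligible), len(index.genes)), dtype=bool)
    for si, gs in enumerate(eligible):
        for g in gs.genes:
            if g in gene_pos:
                member[si, gene_pos[g]] = True
    set_sizes = member.sum(axis=1)
    if (set_sizes == len(index.genes)).any():
        raise ValueError("a gene set covers every selected gene")

    p_arr = pvals.to_numpy(dtype=float)
    thr = snp_significance_threshold(p_arr, config.top_fraction)
    sig_snp = p_arr <= thr

    obs = _corrected_scores(index, index.neglogp, sig_snp, member,
                            set_sizes, config.weight_exponent)

    rng = np.random.default_rng(config.seed)
    B = config.permutations
    perm = np.empty((B, len(eligible)))
    for b in range(B):
        idx = rng.permutation(index.n_snps)
        perm[b] = _corrected_scores(index, index.neglogp[idx], sig_snp[idx],
                                    member, set_sizes,
                                    config.weight_exponent)

    nominal_p = (1 + (perm >= obs[None, :]).sum(axis=0)) / (B + 1)

    # GSEA-style FDR on pathway-normalized positive scores
    pos_mean = np.where((perm > 0).any(axis=0),
                        np.nanmean(np.where(perm > 0, perm, np.nan), axis=0),
                        1.0)
    nes_obs = obs / pos_mean
    nes_perm = perm / pos_mean[None, :]
    pooled = nes_perm.ravel()
    fdr = np.ones(len(eligible))
    positive = nes_obs > 0
    for i in np.flatnonzero(positive):
        num = (pooled >= nes_obs[i]).mean()
        den = (nes_obs >= nes_obs[i]).mean()
        fdr[i] = min(1.0, num / den) if den > 0 else 1.0

    sig_gene_obs = index.significant(sig_snp)
    n_sig = member.astype(float) @ sig_gene_obs.astype(float)
    records = pd.DataFrame({
        "pathway": [gs.name for gs in eligible],
        "source": [gs.description for gs in eligible],
        "es": [float(enrichment_score(ranked, gs.genes,
                                      config.weight_exponent))
               for gs in eligible],
        "es_star": obs,
        "nes": nes_obs,
        "p": nominal_p,
        "fdr": fdr,
        "n_significant": n_sig.astype(int),
        "n_selected": set_sizes.astype(int),
        "n_all": [len(gs.genes) for gs in eligible],
    })
    records["fdr_bh"] = bh_qvalues(records["p"].to_numpy())
    return records


def enrichment_report(records: pd.DataFrame) -> pd.DataFrame:
    """Sort by (FDR, nominal p) and format the gene-count triple a/b/c."""
    bad = records[(records["n_significant"] > records["n_selected"])
                  | (records["n_selected"] > records["n_all"])]
    if len(bad):
        raise ValueError(f"inconsistent gene counts for "
                         f"{bad['pathway'].tolist()}")
    out = records.sort_values(["fdr", "p", "pathway"]).reset_index(drop=True)
    out["genes"] = (out["n_significant"].astype(str) + "/"
                    + out["n_selected"].astype(str) + "/"
                    + out["n_all"].astype(str))
    return out


def run_enrichment(scan_table: pd.DataFrame, snp_info: pd.DataFrame,
                   genes: pd.DataFrame, sets: Sequence[GeneSet],
                   config: EnrichmentConfig = EnrichmentConfig()
                   ) -> pd.DataFrame:
    """Front end: scan output -> mapping -> permutation enrichment report."""
    tested = scan_table.dropna(subset=["p"])
    pvals = pd.Series(tested["p"].to_numpy(), index=tested["snp"].to_numpy())
    gene_map = map_snps_to_genes(snp_info, genes, config.flank)
    records = permutation_fdr(pvals, gene_map, sets, config)
    return enrichment_report(records)
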