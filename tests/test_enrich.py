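import numpy as np
import pandas as pd
import pytest

from oxbalance import (EnrichmentConfig, enrichment_report, enrichment_score,
                       filter_gene_sets, gene_statistics, map_snps_to_genes,
                       permutation_fdr, significance_proportion)
from oxbalance.io_formats import GeneSet


def _genes(rows):
    return pd.DataFrame(rows, columns=["gene", "chrom", "start", "end"])


def _snps(rows):
    return pd.DataFrame(rows, columns=["snp", "chrom", "pos"])


# ---------------------------------------------------------------------------
# SNP -> gene mapping
# ---------------------------------------------------------------------------

def test_mapping_inside_and_flank_boundary():
    genes = _genes([("G1", "chr1", 500_000, 520_000)])
    snps = _snps([
        ("in_body", "chr1", 510_000),
        ("at_flank", "chr1", 620_000),        # end + 100,000: mapped
        ("past_flank", "chr1", 620_001),      # one bp further: not
        ("left_flank", "chr1", 400_000),      # start - 100,000: mapped
        ("left_out", "chr1", 399_999),
    ])
    gm = map_snps_to_genes(snps, genes)
    assert set(gm.loc[0, "snps"]) == {"in_body", "at_flank", "left_flank"}


def test_mapping_chromosome_mismatch_unmapped():
    genes = _genes([("G1", "chr1", 1000, 2000)])
    snps = _snps([("s1", "chrX", 1500)])
    gm = map_snps_to_genes(snps, genes)
    assert gm.loc[0, "snps"] == ()


def test_mapping_equals_all_pairs_oracle():
    """Brute-force interval check over random instances."""
    rng = np.random.default_rng(55)
    for _ in range(300):
        genes = _genes([(f"G{i}", f"chr{rng.integers(1, 3)}",
                         int(s := rng.integers(1, 10**6)),
                         int(s + rng.integers(100, 50_000)))
                        for i in range(10)])
        snps = _snps([(f"s{j}", f"chr{rng.integers(1, 3)}",
                       int(rng.integers(1, 1_200_000)))
                      for j in range(50)])
        flank = int(rng.choice([0, 10_000, 100_000]))
        gm = map_snps_to_genes(snps, genes, flank).set_index("gene")
        for _, g in genes.iterrows():
            expect = {s["snp"] for _, s in snps.iterrows()
                      if s["chrom"] == g["chrom"]
                      and g["start"] - flank <= s["pos"] <= g["end"] + flank}
            assert set(gm.loc[g["gene"], "snps"]) == expect


# ---------------------------------------------------------------------------
# gene statistics
# ---------------------------------------------------------------------------

def test_gene_statistic_is_max_neglog_p():
    genes = _genes([("G1", "chr1", 100, 200)])
    snps = _snps([("a", "chr1", 150), ("b", "chr1", 160)])
    gm = map_snps_to_genes(snps, genes, flank=0)
    ranked = gene_statistics(pd.Series([0.1, 0.001], index=["a", "b"]), gm)
    assert ranked.loc[0, "stat"] == pytest.approx(3.0)


def test_gene_ranking_tie_break_is_alphabetical():
    genes = _genes([(g, "chr1", 100 + 1000 * i, 200 + 1000 * i)
                    for i, g in enumerate(["GB", "GA", "GC"])])
    snps = _snps([(f"s{i}", "chr1", 150 + 1000 * i) for i in range(3)])
    gm = map_snps_to_genes(snps, genes, flank=0)
    ranked = gene_statistics(
        pd.Series([0.5, 0.5, 0.5], index=["s0", "s1", "s2"]), gm)
    assert ranked["gene"].tolist() == ["GA", "GB", "GC"]


def test_gene_statistics_brute_force_toy_scan():
    rng = np.random.default_rng(60)
    genes = _genes([(f"G{i}", "chr1", 1 + 10_000 * i, 5_000 + 10_000 * i)
                    for i in range(5)])
    snps = _snps([(f"s{j}", "chr1", int(rng.integers(1, 55_000)))
                  for j in range(20)])
    p = pd.Series(rng.uniform(1e-6, 1, 20), index=snps["snp"].to_numpy())
    gm = map_snps_to_genes(snps, genes, flank=1_000)
    ranked = gene_statistics(p, gm).set_index("gene")
    for _, g in gm.iterrows():
        if g["snps"]:
            assert ranked.loc[g["gene"], "stat"] == pytest.approx(
                max(-np.log10(p[s]) for s in g["snps"]))
        else:
            assert g["gene"] not in ranked.index


# ---------------------------------------------------------------------------
# gene-set size filter
# ---------------------------------------------------------------------------

def test_size_filter_boundaries():
    ranked = pd.DataFrame({"gene": [f"G{i}" for i in range(250)],
                           "stat": np.linspace(5, 0, 250)})
    sets = [
        GeneSet("S19", "", tuple(f"G{i}" for i in range(19))),
        GeneSet("S20", "", tuple(f"G{i}" for i in range(20))),
        GeneSet("S200", "", tuple(f"G{i}" for i in range(200))),
        GeneSet("S201", "", tuple(f"G{i}" for i in range(201))),
    ]
    kept = {g.name for g in filter_gene_sets(sets, ranked)}
    assert kept == {"S20", "S200"}


def test_size_filter_counts_selected_genes_not_annotated():
    ranked = pd.DataFrame({"gene": [f"G{i}" for i in range(25)],
                           "stat": np.linspace(5, 0, 25)})
    # 25 annotated genes but only 19 selected -> excluded by default
    genes = tuple(f"G{i}" for i in range(19)) + tuple(
        f"X{i}" for i in range(6))
    sets = [GeneSet("S", "", genes),
            GeneSet("OK", "", tuple(f"G{i}" for i in range(25)))]
    kept = {g.name for g in filter_gene_sets(sets, ranked)}
    assert kept == {"OK"}
    cfg = EnrichmentConfig(filter_on="all", permutations=100)
    kept_all = {g.name for g in filter_gene_sets(sets, ranked, cfg)}
    assert kept_all == {"S", "OK"}


def test_empty_filter_result_raises():
    ranked = pd.DataFrame({"gene": ["G0", "G1"], "stat": [1.0, 0.5]})
    with pytest.raises(ValueError, match="size filter"):
        filter_gene_sets([GeneSet("S", "", ("G0",))], ranked)


# ---------------------------------------------------------------------------
# enrichment score
# ---------------------------------------------------------------------------

def test_es_pencil_and_paper_six_genes():
    """Stats 5,4,3,2,1,0; set {first, fourth}: denominator 7, miss step 1/4.

    Running sum: 5/7, 5/7-1/4, 5/7-2/4, 5/7+2/7-2/4, ... max dev = 5/7.
    """
    ranked = pd.DataFrame({"gene": list("ABCDEF"),
                           "stat": [5.0, 4.0, 3.0, 2.0, 1.0, 0.0]})
    es = enrichment_score(ranked, ["A", "D"])
    assert es == pytest.approx(5 / 7)


def test_es_top_k_concentration_approaches_one():
    ranked = pd.DataFrame({"gene": [f"G{i}" for i in range(40)],
                           "stat": np.linspace(20, 0.1, 40)})
    es = enrichment_score(ranked, ["G0", "G1", "G2"])
    assert es > 0.85


def test_es_equal_stats_random_sets_centered_small():
    rng = np.random.default_rng(71)
    ranked = pd.DataFrame({"gene": [f"G{i}" for i in range(50)],
                           "stat": np.ones(50)})
    vals = []
    for _ in range(200):
        members = rng.choice(ranked["gene"], 10, replace=False)
        vals.append(enrichment_score(ranked, members))
    assert abs(np.mean(vals)) < 0.15


def test_es_matches_brute_force_running_sum():
    rng = np.random.default_rng(73)
    for _ in range(50):
        n = int(rng.integers(8, 30))
        ranked = pd.DataFrame({
            "gene": [f"G{i}" for i in range(n)],
            "stat": np.sort(rng.uniform(0, 10, n))[::-1]})
        m = int(rng.integers(1, n - 1))
        members = list(rng.choice(ranked["gene"], m, replace=False))
        w = 1.0
        # independent loop implementation
        in_set = ranked["gene"].isin(members).to_numpy()
        denom = np.abs(ranked["stat"].to_numpy()[in_set] ** w).sum()
        running, best = 0.0, 0.0
        for i in range(n):
            if in_set[i]:
                running += abs(ranked["stat"][i]) ** w / denom
            else:
                running -= 1 / (n - m)
            if abs(running) > abs(best):
                best = running
        assert enrichment_score(ranked, members, w) == pytest.approx(
            best, abs=1e-10)


def test_es_no_overlap_rejected():
    ranked = pd.DataFrame({"gene": ["A", "B"], "stat": [1.0, 0.5]})
    with pytest.raises(ValueError, match="overlap"):
        enrichment_score(ranked, ["Z"])


# ---------------------------------------------------------------------------
# significance proportion
# ---------------------------------------------------------------------------

def test_k_equals_one_when_proportions_match():
    ranked = pd.DataFrame({"gene": [f"G{i}" for i in range(40)],
                           "stat": np.linspace(4, 0, 40)})
    sig = [f"G{i}" for i in range(0, 40, 4)]          # 25% overall
    members = [f"G{i}" for i in range(0, 8)]          # 2 of 8 significant
    assert significance_proportion(members, ranked, sig) == pytest.approx(1.0)


def test_k_zero_when_no_significant_member():
    ranked = pd.DataFrame({"gene": [f"G{i}" for i in range(10)],
                           "stat": np.linspace(4, 0, 10)})
    assert significance_proportion(["G5", "G6"], ranked, ["G0"]) == 0.0


def test_k_arithmetic_oracle_ratio_of_proportions():
    ranked = pd.DataFrame({"gene": [f"G{i}" for i in range(400)],
                           "stat": np.linspace(4, 0, 400)})
    sig = [f"G{i}" for i in range(100)]                 # 100/400 overall
    members = [f"G{i}" for i in range(90, 110)]         # 10 of 20
    assert significance_proportion(members, ranked, sig) == pytest.approx(2.0)


def test_k_undefined_when_nothing_significant():
    ranked = pd.DataFrame({"gene": ["A", "B", "C"],
                           "stat": [3.0, 2.0, 1.0]})
    with pytest.raises(ZeroDivisionError):
        significance_proportion(["A"], ranked, [])


# ---------------------------------------------------------------------------
# permutation FDR
# ---------------------------------------------------------------------------

def _toy_instance(rng, n_genes=60, n_snps=240, planted=None):
    genes = _genes([(f"G{i:02d}", "chr1", 1 + 200_000 * i,
                     20_000 + 200_000 * i) for i in range(n_genes)])
    snp_rows, pvals = [], {}
    for j in range(n_snps):
        gi = j % n_genes
        pos = 1 + 200_000 * gi + int(rng.integers(0, 20_000))
        snp_rows.append((f"s{j}", "chr1", pos))
        pvals[f"s{j}"] = rng.uniform()
    if planted:
        for j, p in planted.items():
            pvals[f"s{j}"] = p
    snps = _snps(snp_rows)
    return genes, snps, pd.Series(pvals)


def test_permutation_p_floor_for_extreme_pathway():
    rng = np.random.default_rng(80)
    # plant tiny p-values on the SNPs of genes G00..G19
    planted = {j: 1e-9 for j in range(20)}
    genes, snps, pvals = _toy_instance(rng, planted=planted)
    gm = map_snps_to_genes(snps, genes, flank=0)
    sets = [GeneSet("HOT", "", tuple(f"G{i:02d}" for i in range(20))),
            GeneSet("COLD", "", tuple(f"G{i:02d}" for i in range(20, 40)))]
    cfg = EnrichmentConfig(permutations=100, seed=1)
    rec = permutation_fdr(pvals, gm, sets, cfg).set_index("pathway")
    assert rec.loc["HOT", "p"] == pytest.approx(1 / 101)
    assert rec.loc["HOT", "fdr"] < rec.loc["COLD", "fdr"]
    assert rec.loc["HOT", "n_significant"] >= 10


def test_permutation_deterministic_given_seed():
    rng = np.random.default_rng(81)
    genes, snps, pvals = _toy_instance(rng)
    gm = map_snps_to_genes(snps, genes, flank=0)
    sets = [GeneSet("S1", "", tuple(f"G{i:02d}" for i in range(25))),
            GeneSet("S2", "", tuple(f"G{i:02d}" for i in range(30, 55)))]
    cfg = EnrichmentConfig(permutations=120, seed=9)
    a = permutation_fdr(pvals, gm, sets, cfg)
    b = permutation_fdr(pvals, gm, sets, cfg)
    pd.testing.assert_frame_equal(a, b)


def test_permutation_p_converges_with_more_permutations():
    rng = np.random.default_rng(82)
    planted = {j: 5e-4 for j in range(8)}
    genes, snps, pvals = _toy_instance(rng, planted=planted)
    gm = map_snps_to_genes(snps, genes, flank=0)
    sets = [GeneSet("S1", "", tuple(f"G{i:02d}" for i in range(25))),
            GeneSet("S2", "", tuple(f"G{i:02d}" for i in range(30, 55)))]
    p1 = permutation_fdr(pvals, gm, sets,
                         EnrichmentConfig(permutations=200, seed=3))
    p2 = permutation_fdr(pvals, gm, sets,
                         EnrichmentConfig(permutations=400, seed=3))
    for s in ("S1", "S2"):
        a = p1.set_index("pathway").loc[s, "p"]
        b = p2.set_index("pathway").loc[s, "p"]
        mc = 3 * np.sqrt(max(a, 1 / 201) * (1 - a) / 200)
        assert abs(a - b) <= mc + 0.01


def test_small_permutation_count_rejected():
    with pytest.raises(ValueError, match="100"):
        EnrichmentConfig(permutations=50)


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

def _record(pathway, fdr, p, sig=2, sel=10, tot=12):
    return {"pathway": pathway, "source": "KEGG", "es": 0.5,
            "es_star": 0.5, "nes": 1.0, "p": p, "fdr": fdr,
            "n_significant": sig, "n_selected": sel, "n_all": tot,
            "fdr_bh": p}


def test_report_sorted_by_fdr_then_p():
    records = pd.DataFrame([_record("A", 0.02, 0.01),
                            _record("B", 0.05, 0.01),
                            _record("C", 0.01, 0.005)])
    out = enrichment_report(records)
    assert out["pathway"].tolist() == ["C", "A", "B"]
    assert out["genes"].tolist() == ["2/10/12"] * 3


def test_report_rejects_inconsistent_counts():
    records = pd.DataFrame([_record("A", 0.02, 0.01, sig=11, sel=10)])
    with pytest.raises(ValueError, match="inconsistent"):
        enrichment_report(records)


def test_report_round_trip(tmp_path):
    from oxbalance import io_formats as iof
    records = pd.DataFrame([_record("A", 0.02, 0.01),
                            _record("B", 0.05, 0.02)])
    out = enrichment_report(records)
    iof.write_table(out, tmp_path / "enrich.tsv", params={"seed": 1})
    back = iof.read_table(tmp_path / "enrich.tsv")
    pd.testing.assert_frame_equal(back, out, check_dtype=False)
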