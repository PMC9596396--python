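import numpy as np
import pandas as pd
import pytest

import tumorhet as th
from tumorhet.datasets import GeneSetCollection
from tumorhet.scoring import (
    StandardizedMatrix,
    case_enrichment_summary,
    commonly_enriched,
    ssgsea_score_collection,
    zscore_set_score,
)
from tumorhet.simulate import HistotypeSpec, PlantedSet, SimulationConfig

from conftest import make_dataset


def std_from_z(z_values, gene_ids=None, sample_ids=None):
    z = np.asarray(z_values, dtype=float)
    gene_ids = gene_ids or [f"G{i}" for i in range(1, z.shape[0] + 1)]
    sample_ids = sample_ids or [f"S{j}" for j in range(1, z.shape[1] + 1)]
    frame = pd.DataFrame(z, index=pd.Index(gene_ids), columns=sample_ids)
    return StandardizedMatrix(
        z=frame, scope="all_samples", means=frame * 0, sds=frame * 0 + 1
    )


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------

def test_standardize_hand_example():
    """(4, 6, 8) -> (-1, 0, 1): sd uses the unbiased (n-1) denominator."""
    ds = make_dataset([[4.0, 6.0, 8.0]], cases=["c1", "c1", "c2"])
    std = th.standardize(ds)
    np.testing.assert_allclose(std.z.iloc[0], [-1.0, 0.0, 1.0])


def test_standardize_constant_gene_zeroed():
    ds = make_dataset([[6.0, 6.0, 6.0], [1.0, 2.0, 3.0]], cases=["c1", "c1", "c2"])
    std = th.standardize(ds)
    np.testing.assert_array_equal(std.z.iloc[0], 0.0)
    assert std.z.iloc[1].std(ddof=1) == pytest.approx(1.0)


def test_standardize_per_histotype_blocks_centered():
    rng = np.random.default_rng(0)
    ds = make_dataset(
        rng.normal(6, 2, size=(10, 8)),
        cases=["c1", "c1", "c2", "c2", "c3", "c3", "c4", "c4"],
        histotypes=["HB"] * 4 + ["WT"] * 4,
    )
    std = th.standardize(ds, scope="per_histotype")
    for hist in ("HB", "WT"):
        block = std.z.loc[:, (ds.histotypes == hist).to_numpy()]
        np.testing.assert_allclose(block.mean(axis=1), 0.0, atol=1e-8)
        np.testing.assert_allclose(block.std(axis=1, ddof=1), 1.0, atol=1e-8)


def test_standardize_singleton_scope_group_rejected():
    ds = make_dataset(
        [[1.0, 2.0, 3.0]],
        cases=["c1", "c1", "c2"],
        histotypes=["HB", "HB", "WT"],
    )
    with pytest.raises(ValueError, match="fewer than 2"):
        th.standardize(ds, scope="per_histotype")


# ---------------------------------------------------------------------------
# z-score set scores
# ---------------------------------------------------------------------------

def test_zscore_hand_arithmetic():
    """z = (1, -1, 2, 0) over a 4-gene set -> S = 2 / sqrt(4) = 1.0."""
    std = std_from_z([[1.0], [-1.0], [2.0], [0.0]])
    out = zscore_set_score(std, GeneSetCollection({"S": ["G1", "G2", "G3", "G4"]}))
    assert out.scores.loc["S"].iloc[0] == pytest.approx(1.0)
    assert bool(out.enriched.loc["S"].iloc[0])


def test_zscore_zero_set_not_enriched():
    std = std_from_z([[0.0], [0.0]])
    out = zscore_set_score(std, GeneSetCollection({"S": ["G1", "G2"]}))
    assert out.scores.loc["S"].iloc[0] == 0.0
    assert not bool(out.enriched.loc["S"].iloc[0])


def test_zscore_singleton_set_identity():
    std = std_from_z([[0.7, -0.2], [1.5, 0.1]])
    out = zscore_set_score(std, GeneSetCollection({"S": ["G2"]}))
    np.testing.assert_allclose(out.scores.loc["S"], std.z.loc["G2"])


def test_zscore_unmatched_members_dropped_and_missing_flagged():
    std = std_from_z([[1.0], [1.0]])
    sets = GeneSetCollection({"S": ["G1", "NOPE"], "GONE": ["X", "Y"]})
    out = zscore_set_score(std, sets)
    assert out.n_genes_used["S"] == 1
    assert out.scores.loc["S"].iloc[0] == pytest.approx(1.0)  # sqrt uses matched count
    assert out.missing_sets == ["GONE"]
    assert "GONE" not in out.scores.index


def test_zscore_full_universe_matches_direct_sum(random_dataset):
    std = th.standardize(random_dataset)
    universe = GeneSetCollection({"ALL": list(random_dataset.gene_ids)})
    out = zscore_set_score(std, universe)
    expected = std.z.sum(axis=0) / np.sqrt(random_dataset.n_genes)
    np.testing.assert_allclose(out.scores.loc["ALL"], expected, atol=1e-10)


def test_scores_location_invariant(random_dataset):
    """Adding a constant to one gene's expression changes nothing."""
    sets = GeneSetCollection({"S": list(random_dataset.gene_ids[:7])})
    base = zscore_set_score(th.standardize(random_dataset), sets).scores
    shifted = random_dataset.copy()
    shifted.values.iloc[3] += 11.0
    after = zscore_set_score(th.standardize(shifted), sets).scores
    np.testing.assert_allclose(after, base, atol=1e-10)


# ---------------------------------------------------------------------------
# ssGSEA
# ---------------------------------------------------------------------------

def ssgsea_oracle(values, gene_ids, members, alpha):
    """Naive running-sum enumeration of the un-normalized ssGSEA score."""
    order = sorted(range(len(values)), key=lambda i: (-values[i], gene_ids[i]))
    n = len(values)
    in_set = [gene_ids[i] in members for i in order]
    w = [(n - r) ** alpha for r in range(n)]  # rank statistic N - rank + 1
    tot_in = sum(wi for wi, f in zip(w, in_set) if f)
    n_out = sum(1 for f in in_set if not f)
    score, cum_in, cum_out = 0.0, 0.0, 0.0
    for wi, f in zip(w, in_set):
        if f:
            cum_in += wi / tot_in
        elif n_out:
            cum_out += 1.0 / n_out
        score += cum_in - cum_out
    return score


def test_ssgsea_matches_running_sum_oracle():
    rng = np.random.default_rng(5)
    ds = make_dataset(rng.normal(7, 2, size=(25, 6)), cases=["c1"] * 3 + ["c2"] * 3)
    members = list(ds.gene_ids[3:12])
    got = th.ssgsea_score(ds, members, alpha=0.25)
    for sid in ds.sample_ids:
        want = ssgsea_oracle(
            ds.values[sid].to_numpy(), list(ds.gene_ids), set(members), 0.25
        )
        assert got[sid] == pytest.approx(want, abs=1e-10)


def test_ssgsea_all_genes_set_is_maximal_positive():
    rng = np.random.default_rng(6)
    ds = make_dataset(rng.normal(7, 2, size=(10, 2)))
    got = th.ssgsea_score(ds, list(ds.gene_ids), alpha=0.25)
    for sid in ds.sample_ids:
        want = ssgsea_oracle(
            ds.values[sid].to_numpy(), list(ds.gene_ids), set(ds.gene_ids), 0.25
        )
        assert got[sid] == pytest.approx(want, abs=1e-10)
        assert got[sid] > 0


def test_ssgsea_identical_samples_identical_scores():
    col = np.arange(8, dtype=float)
    ds = make_dataset(np.column_stack([col, col]))
    got = th.ssgsea_score(ds, ["G2", "G5", "G8"])
    assert got.iloc[0] == got.iloc[1]


def test_ssgsea_ranks_top_genes_above_bottom_genes():
    """Set genes at the top of sample A and the bottom of sample B."""
    values = np.array(
        [
            [9.0, 1.0],
            [8.0, 2.0],
            [3.0, 7.0],
            [2.0, 8.0],
            [5.0, 5.0],
        ]
    )
    ds = make_dataset(values)
    got = th.ssgsea_score(ds, ["G1", "G2"])
    assert got["S1"] > got["S2"]


def test_ssgsea_alpha0_invariant_to_monotone_transform():
    rng = np.random.default_rng(8)
    ds = make_dataset(rng.normal(7, 2, size=(20, 4)))
    members = list(ds.gene_ids[:6])
    base = th.ssgsea_score(ds, members, alpha=0.0)
    warped = make_dataset(np.exp(ds.values.to_numpy() / 3.0))
    after = th.ssgsea_score(warped, members, alpha=0.0)
    np.testing.assert_allclose(after, base.to_numpy(), atol=1e-10)


def test_ssgsea_too_few_matched_genes_rejected(random_dataset):
    with pytest.raises(ValueError, match=">= 2"):
        th.ssgsea_score(random_dataset, ["G1", "NOT_THERE"])


def test_ssgsea_sample_ranking_agrees_with_gseapy():
    """Independent implementation check: gseapy's un-normalized ssGSEA ES
    orders samples the same way (its tie/normalisation details differ, so
    only the ranking is compared)."""
    gseapy = pytest.importorskip("gseapy")
    from scipy.stats import spearmanr

    rng = np.random.default_rng(0)
    ds = make_dataset(rng.normal(8, 2, size=(60, 10)), cases=[f"c{j // 2}" for j in range(10)])
    members = list(ds.gene_ids[:12])
    mine = th.ssgsea_score(ds, members, alpha=0.25)
    res = gseapy.ssgsea(
        data=ds.values,
        gene_sets={"SET1": members},
        outdir=None,
        sample_norm_method=None,
        correl_norm_type="rank",
        weight=0.25,
        min_size=2,
        no_plot=True,
        threads=1,
    )
    theirs = res.res2d.set_index("Name")["ES"].astype(float).loc[mine.index]
    assert spearmanr(mine, theirs).statistic > 0.99


# ---------------------------------------------------------------------------
# enrichment summaries and decision rules
# ---------------------------------------------------------------------------

def _matrix_from_scores(scores, annotations):
    frame = pd.DataFrame(scores)
    from tumorhet.scoring import SetScoreMatrix

    return SetScoreMatrix(
        scores=frame,
        method="zscore",
        enriched=frame > 0,
        n_genes_used=pd.Series({s: 5 for s in frame.index}),
    )


def test_case_counts():
    ann = pd.DataFrame(
        {"case_id": ["c1"] * 4, "histotype": ["HB"] * 4},
        index=[f"S{i}" for i in range(1, 5)],
    )
    mat = _matrix_from_scores(
        {"S1": {"HGS": 0.2}, "S2": {"HGS": 0.1}, "S3": {"HGS": -0.3}, "S4": {"HGS": 0.4}},
        ann,
    )
    summary = case_enrichment_summary(mat, ann)
    row = summary.by_case.iloc[0]
    assert (row["n_enriched"], row["n_samples"]) == (3, 4)
    assert row["fraction"] == pytest.approx(0.75)


def test_all_negative_case_counts_zero():
    ann = pd.DataFrame(
        {"case_id": ["c1"] * 4, "histotype": ["HB"] * 4},
        index=[f"S{i}" for i in range(1, 5)],
    )
    mat = _matrix_from_scores({f"S{i}": {"HGS": -0.1 * i} for i in range(1, 5)}, ann)
    summary = case_enrichment_summary(mat, ann)
    assert summary.by_case.iloc[0]["n_enriched"] == 0


@pytest.mark.parametrize(
    "n_enriched,n_samples,expected",
    [(16, 20, True), (15, 20, False), (16, 19, True), (0, 20, False)],
)
def test_commonly_enriched_threshold(n_enriched, n_samples, expected):
    """The 'at least 16 of 19-20 samples' commonality rule at min_fraction 0.8."""
    from tumorhet.scoring import EnrichmentSummary

    by_hist = pd.DataFrame(
        [("HGS", "HB", n_enriched, n_samples, n_enriched / n_samples)],
        columns=["set", "histotype", "n_enriched", "n_samples", "fraction"],
    )
    summary = EnrichmentSummary(by_case=pd.DataFrame(), by_histotype=by_hist)
    flags = commonly_enriched(summary, min_fraction=0.8)
    assert bool(flags.loc["HGS", "HB"]) is expected


def test_commonly_enriched_bad_fraction_rejected():
    from tumorhet.scoring import EnrichmentSummary

    summary = EnrichmentSummary(
        by_case=pd.DataFrame(),
        by_histotype=pd.DataFrame(
            [("S", "HB", 1, 2, 0.5)],
            columns=["set", "histotype", "n_enriched", "n_samples", "fraction"],
        ),
    )
    with pytest.raises(ValueError):
        commonly_enriched(summary, min_fraction=0.0)


def test_null_enrichment_fraction_near_half():
    """Without planted signal, z-scores are symmetric about 0, so about half
    of all calls are 'enriched'."""
    cfg = SimulationConfig(
        n_genes=300,
        histotypes=(HistotypeSpec("T", 5, 4, case_sd=0.4, sample_sd=0.4),),
        histotype_sd=0.0,
        baseline_sd=1.0,
    )
    sets = GeneSetCollection({f"SET{i}": [f"G{j:04d}" for j in range(i * 30 + 1, i * 30 + 31)] for i in range(5)})
    fractions = []
    for seed in range(10):
        ds, _, _ = th.generate_dataset(cfg, seed=seed)
        res = th.GeneSetScoring(ds, sets).fit()
        fractions.append(res.enriched.to_numpy().mean())
    assert np.mean(fractions) == pytest.approx(0.5, abs=0.1)


def test_case_scoped_planted_signal_recovered():
    """A shift planted in one case lights up that case; sibling cases stay
    near chance."""
    cfg = SimulationConfig(
        n_genes=400,
        histotypes=(HistotypeSpec("HB", 5, 4, case_sd=0.3, sample_sd=0.3),),
        histotype_sd=0.0,
        baseline_sd=1.0,
        planted_sets=(PlantedSet("UP", 30, "case", ("HB_c1",), 1.0),),
    )
    target_fracs, sibling_fracs = [], []
    for seed in range(10):
        ds, gmt, _ = th.generate_dataset(cfg, seed=seed)
        res = th.GeneSetScoring(ds, gmt).fit()
        by_case = res.case_summary().set_index("case_id")
        target_fracs.append(by_case.loc["HB_c1", "fraction"])
        sibling_fracs.extend(by_case.drop("HB_c1")["fraction"])
    assert np.mean(target_fracs) >= 0.95
    assert np.mean(sibling_fracs) < 0.6


def test_model_ssgsea_path_and_summary(random_dataset):
    sets = GeneSetCollection(
        {"A": list(random_dataset.gene_ids[:8]), "B": list(random_dataset.gene_ids[8:20])}
    )
    res = th.GeneSetScoring(random_dataset, sets, method="ssgsea").fit()
    assert res.scores.shape == (2, random_dataset.n_samples)
    assert "ssgsea" in res.summary()
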