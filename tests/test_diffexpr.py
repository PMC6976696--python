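"""DE stage: normalization, exact nonparametric tests, seed selection, ddCT."""

from itertools import combinations, product

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ppimod import (
    average_replicates,
    ddct_relative_expression,
    differential_expression,
    mann_whitney_u,
    nb_sample,
    select_seeds,
    size_factors,
    wilcoxon_signed_rank,
)
from ppimod.diffexpr import DiffExprError


# ---------------------------------------------------------------------------
# independent enumeration oracles
# ---------------------------------------------------------------------------

def _u_stat(xs, ys):
    return sum((a > b) + 0.5 * (a == b) for a in xs for b in ys)


def mw_enum_p(x, y, alternative):
    """Exact Mann-Whitney p by enumerating every group labeling of the pool."""
    pooled = list(x) + list(y)
    n, m = len(x), len(y)
    obs = _u_stat(x, y)
    center = n * m / 2.0
    us = []
    for comb in combinations(range(n + m), n):
        chosen = set(comb)
        xs = [pooled[i] for i in comb]
        ys = [pooled[i] for i in range(n + m) if i not in chosen]
        us.append(_u_stat(xs, ys))
    us = np.array(us)
    if alternative == "greater":
        hits = us >= obs - 1e-9
    elif alternative == "less":
        hits = us <= obs + 1e-9
    else:
        hits = np.abs(us - center) >= abs(obs - center) - 1e-9
    return hits.mean()


def wsr_enum_p(diffs, alternative):
    """Exact signed-rank p by enumerating all sign assignments."""
    d = np.asarray(diffs, float)
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    total = ranks.sum()
    obs = ranks[d > 0].sum()
    center = total / 2.0
    ws = np.array(
        [sum(r for r, s in zip(ranks, signs) if s > 0)
         for signs in product([1, -1], repeat=len(d))]
    )
    if alternative == "greater":
        hits = ws >= obs - 1e-9
    elif alternative == "less":
        hits = ws <= obs + 1e-9
    else:
        hits = np.abs(ws - center) >= abs(obs - center) - 1e-9
    return hits.mean()


# ---------------------------------------------------------------------------
# size factors and replicate averaging
# ---------------------------------------------------------------------------

def test_size_factors_exact_scaling():
    counts = pd.DataFrame({"s1": [10, 20, 30], "s2": [20, 40, 60]}, index=list("abc"))
    f = size_factors(counts)
    assert f["s2"] / f["s1"] == pytest.approx(2.0)
    assert np.exp(np.log(f).mean()) == pytest.approx(1.0)


def test_size_factors_single_sample_is_one():
    counts = pd.DataFrame({"s1": [5, 9, 2]}, index=list("abc"))
    assert size_factors(counts)["s1"] == pytest.approx(1.0)


def test_size_factors_recover_known_depths(rng):
    depths = np.array([0.5, 1.0, 2.0, 4.0])
    mu = 10 ** rng.uniform(1.5, 3, size=200)
    counts = pd.DataFrame(
        {f"s{j}": nb_sample(rng, mu * d, 0.05) for j, d in enumerate(depths)}
    )
    est = size_factors(counts).to_numpy()
    truth = depths / np.exp(np.log(depths).mean())
    assert np.all(np.abs(est / truth - 1) < 0.10)


def test_size_factors_error_cases():
    with pytest.raises(DiffExprError, match="all-zero"):
        size_factors(pd.DataFrame({"s1": [1, 2], "s2": [0, 0]}))
    with pytest.raises(DiffExprError, match="no reference genes"):
        size_factors(pd.DataFrame({"s1": [1, 0], "s2": [0, 1]}))


def _meta(sample_specs):
    rows = []
    for sid, donor, treat, rep in sample_specs:
        rows.append(
            {"sample_id": sid, "donor": donor, "phenotype": "non_asthmatic",
             "treatment": treat, "timepoint": "t3h", "replicate": rep}
        )
    return pd.DataFrame(rows).set_index("sample_id")


def test_average_replicates_examples_and_loop_oracle(rng):
    counts = pd.DataFrame(
        rng.integers(0, 100, size=(20, 4)),
        index=[f"g{i}" for i in range(20)],
        columns=["a1", "a2", "b1", "b2"],
    )
    meta = _meta([("a1", "D1", "control", 1), ("a2", "D1", "control", 2),
                  ("b1", "D2", "control", 1), ("b2", "D2", "control", 2)])
    avg, avg_meta = average_replicates(counts, meta)
    assert avg.shape[1] == 2 and len(avg_meta) == 2
    for col, members in [(avg.columns[0], ["a1", "a2"]), (avg.columns[1], ["b1", "b2"])]:
        # explicit loop oracle
        for gi in range(20):
            expected = sum(counts.loc[f"g{gi}", m] for m in members) / len(members)
            assert avg.loc[f"g{gi}", col] == pytest.approx(expected)
    # identical replicates: averaging is the identity
    counts2 = counts.copy()
    counts2["a2"] = counts2["a1"]
    avg2, _ = average_replicates(counts2, meta)
    assert np.allclose(avg2.iloc[:, 0], counts2["a1"])


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def test_mw_complete_separation_minimizes_u():
    u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
    assert u == 0
    assert p == pytest.approx(2 / 20)  # both extreme labelings of C(6,3)=20


def test_mw_identical_groups_two_sided_p_is_one():
    _, p = mann_whitney_u([1, 2, 3], [1, 2, 3])
    assert p == pytest.approx(1.0)


@pytest.mark.parametrize("alternative", ["two-sided", "greater", "less"])
@pytest.mark.parametrize("n,m", [(1, 3), (2, 2), (3, 3), (4, 2), (5, 5), (6, 6)])
def test_mw_exact_matches_enumeration_oracle(rng, n, m, alternative):
    for _ in range(5):
        pooled = rng.permutation(np.arange(1, n + m + 1, dtype=float))
        x, y = list(pooled[:n]), list(pooled[n:])
        _, p = mann_whitney_u(x, y, alternative)
        assert p == pytest.approx(mw_enum_p(x, y, alternative), abs=1e-12)


def test_mw_matches_scipy_exact():
    x, y = [1.0, 4.0, 6.0, 7.0], [2.0, 3.0, 5.0, 8.0]
    _, p = mann_whitney_u(x, y, "two-sided")
    ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    assert p == pytest.approx(ref.pvalue, abs=1e-12)


def test_mw_exact_and_approx_agree_at_boundary(rng):
    for _ in range(20):
        pooled = rng.normal(size=12)
        x, y = pooled[:6], pooled[6:]
        _, p_exact = mann_whitney_u(x, y, exact_limit=12)
        _, p_approx = mann_whitney_u(x, y, exact_limit=0)
        assert abs(p_exact - p_approx) < 0.02


def test_mw_empty_group_errors():
    with pytest.raises(DiffExprError, match="empty group"):
        mann_whitney_u([], [1.0])


# ---------------------------------------------------------------------------
# Wilcoxon signed rank
# ---------------------------------------------------------------------------

def test_wilcoxon_all_positive_differences():
    pairs = [(2.0, 1.0), (4.0, 2.0), (6.0, 3.0)]  # diffs +1,+2,+3
    w, p = wilcoxon_signed_rank(pairs, "greater")
    assert w == 0  # negative rank sum
    assert p == pytest.approx(1 / 8)  # one of 2**3 sign assignments as extreme


def test_wilcoxon_antisymmetric_two_sided_p_one():
    _, p = wilcoxon_signed_rank([(1.0, 0.0), (0.0, 1.0)], "two-sided")
    assert p == pytest.approx(1.0)


@pytest.mark.parametrize("alternative", ["two-sided", "greater", "less"])
@pytest.mark.parametrize("k", [1, 2, 4, 7, 10])
def test_wilcoxon_exact_matches_sign_enumeration(rng, k, alternative):
    for _ in range(5):
        d = rng.permutation(np.arange(1.0, k + 1)) * rng.choice([-1, 1], size=k)
        pairs = np.column_stack([d, np.zeros(k)])
        _, p = wilcoxon_signed_rank(pairs, alternative)
        assert p == pytest.approx(wsr_enum_p(d, alternative), abs=1e-12)


def test_wilcoxon_exact_handles_tied_magnitudes(rng):
    d = np.array([1.0, 1.0, -2.0, 3.0, 3.0])
    pairs = np.column_stack([d, np.zeros(5)])
    _, p = wilcoxon_signed_rank(pairs, "two-sided")
    assert p == pytest.approx(wsr_enum_p(d, "two-sided"), abs=1e-12)


def test_wilcoxon_degenerate_pairs_error():
    with pytest.raises(DiffExprError, match="degenerate pairs"):
        wilcoxon_signed_rank([(1.0, 1.0), (2.0, 2.0)])


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------

def _two_group_design(n_per_group):
    specs = []
    for i in range(n_per_group):
        specs.append((f"t{i}", f"D{i}", "compressed", 1))
    for i in range(n_per_group):
        specs.append((f"c{i}", f"E{i}", "control", 1))
    return _meta(specs)


def test_de_null_gene_has_unit_fc_and_no_direction():
    meta = _two_group_design(3)
    counts = pd.DataFrame(
        {sid: [50.0] for sid in meta.index}, index=["g1"]
    )
    de = differential_expression(
        counts, meta, {"treatment": "compressed"}, {"treatment": "control"},
        paired=False, normalize=False, average=False,
    )
    assert de.loc["g1", "fc"] == pytest.approx(1.0)
    assert de.loc["g1", "direction"] == "none"
    seeds = select_seeds(de, 1.5, 1.0)
    assert not seeds.genes


def test_de_noiseless_planted_fold_change():
    """A clean 4-fold gene attains fc ~ 4 and the design's minimum exact p."""
    meta = _two_group_design(6)
    base = np.arange(6, dtype=float) * 0.01
    counts = pd.DataFrame(
        {f"t{i}": [400 + base[i]] for i in range(6)} | {f"c{i}": [100 + base[i]] for i in range(6)},
        index=["g1"],
    )
    de = differential_expression(
        counts, meta, {"treatment": "compressed"}, {"treatment": "control"},
        paired=False, normalize=False, average=False,
    )
    fc = de.loc["g1", "fc"]
    assert (400 + 0.5) / (100 + 0.5) * 0.99 < fc < (400 + 0.5) / (100 + 0.5) * 1.01
    assert de.loc["g1", "p"] == pytest.approx(2 / 924)  # 2 extreme of C(12,6) labelings


def test_de_swapping_contrast_inverts_fc_and_keeps_p(rng, small_study):
    _, _, counts, meta, _ = small_study
    sub = counts.iloc[:40]
    a, b = {"treatment": "compressed"}, {"treatment": "control"}
    de_ab = differential_expression(sub, meta, a, b, paired=True)
    de_ba = differential_expression(sub, meta, b, a, paired=True)
    assert np.allclose(de_ab["fc"] * de_ba["fc"], 1.0, rtol=1e-9)
    assert np.allclose(de_ab["p"], de_ba["p"])


def test_de_paired_requires_shared_donors():
    meta = _two_group_design(3)  # donors differ between arms
    counts = pd.DataFrame(
        np.arange(6, dtype=float).reshape(1, 6) + 10, index=["g1"], columns=meta.index
    )
    with pytest.raises(DiffExprError, match="no donors shared"):
        differential_expression(
            counts, meta, {"treatment": "compressed"}, {"treatment": "control"},
            paired=True, normalize=False, average=False,
        )


def test_de_unknown_group_errors(small_study):
    _, _, counts, meta, _ = small_study
    with pytest.raises(DiffExprError, match="group_b"):
        differential_expression(
            counts.iloc[:5], meta, {"treatment": "compressed"}, {"treatment": "nope"}
        )


# ---------------------------------------------------------------------------
# seed selection
# ---------------------------------------------------------------------------

def _de_table(fcs, ps):
    fcs = np.asarray(fcs, float)
    return pd.DataFrame(
        {"fc": fcs, "log2fc": np.log2(fcs), "p": ps,
         "direction": np.where(fcs > 1, "up", np.where(fcs < 1, "down", "none"))},
        index=[f"g{i}" for i in range(len(fcs))],
    )


def test_select_seeds_threshold_examples():
    de = _de_table([2.0, 1.5], [0.01, 0.01])
    assert select_seeds(de, 1.87, 0.05).genes == {"g0"}
    de_down = _de_table([0.5], [0.01])
    s = select_seeds(de_down, 1.87, 0.05)
    assert s.genes == {"g0"} and s.n_down == 1 and s.n_up == 0


def test_select_seeds_matches_brute_force_filter(rng):
    fcs = 2.0 ** rng.normal(0, 1.2, size=500)
    ps = rng.uniform(0, 1, size=500)
    de = _de_table(fcs, ps)
    got = select_seeds(de, 1.87, 0.05).genes
    oracle = {
        f"g{i}"
        for i in range(500)
        if ps[i] <= 0.05 and (fcs[i] >= 1.87 or fcs[i] <= 1 / 1.87)
    }
    assert got == oracle


def test_select_seeds_monotone_in_cutoffs(rng):
    de = _de_table(2.0 ** rng.normal(0, 1, 200), rng.uniform(0, 1, 200))
    strict = select_seeds(de, 1.87, 0.05).genes
    relaxed_fc = select_seeds(de, 1.67, 0.05).genes
    relaxed_p = select_seeds(de, 1.87, 0.10).genes
    assert strict <= relaxed_fc and strict <= relaxed_p


def test_select_seeds_invalid_cutoff():
    with pytest.raises(DiffExprError, match="fc_cutoff"):
        select_seeds(_de_table([2.0], [0.01]), 0.9)


# ---------------------------------------------------------------------------
# ddCT
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "cts,expected",
    [((20, 20, 20, 20), 1.0), ((24, 20, 25, 20), 2.0), ((25, 20, 27, 20), 4.0)],
)
def test_ddct_relative_expression(cts, expected):
    assert ddct_relative_expression(*cts) == pytest.approx(expected)


def test_ddct_rejects_non_finite():
    with pytest.raises(DiffExprError, match="finite"):
        ddct_relative_expression(np.nan, 20, 20, 20)
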