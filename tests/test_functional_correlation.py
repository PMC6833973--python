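"""Functional fixture parsing, trend fitting and association tests."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from vsdflex.functional_correlation import (
    FitResult,
    TableParseError,
    class_association,
    fit_modified_exponential,
    load_functional_table,
    midpoint,
    parse_value,
    rank_correlation,
    read_functional_table,
    write_functional_table,
)


class TestFixtureParsing:
    def test_hhv1_row(self):
        records = load_functional_table()
        hv1 = next(
            r for r in records if r.channel == "hHv1" and r.source_table == "table1"
        )
        assert hv1.s3_index == pytest.approx(1.40)
        assert hv1.charge_e0 == (6.0, 6.0)
        assert hv1.q10_act == (6.0, 9.0)
        assert hv1.q10_inact is None

    def test_shaker_interval_charge(self):
        records = load_functional_table()
        shaker = next(
            r
            for r in records
            if r.channel.startswith("Shaker") and r.source_table == "table1"
        )
        assert shaker.charge_e0 == (12.0, 16.0)
        assert midpoint(shaker.charge_e0) == pytest.approx(14.0)

    def test_nd_cells_are_absent(self):
        records = load_functional_table()
        kv12 = next(r for r in records if r.channel == "Kv1.2")
        assert kv12.q10_act is None and kv12.q10_inact is None

    def test_cnga1_is_most_flexible_s3(self):
        records = [r for r in load_functional_table() if r.source_table == "table1"]
        best = max(
            (r for r in records if r.s3_index is not None), key=lambda r: r.s3_index
        )
        assert best.channel == "CNGA1"

    def test_table2_mechanosensitive_flags(self):
        records = [r for r in load_functional_table() if r.source_table == "table2"]
        assert len(records) == 9
        assert all(r.mechanosensitive for r in records)
        hv1 = next(r for r in records if r.channel == "hHv1")
        assert hv1.dv12_shift == (-14.4, -14.4)

    @pytest.mark.parametrize(
        "cell,expected",
        [
            ("n.d.", None),
            ("-", None),
            ("~ 4", (4.0, 4.0)),
            ("12 to 16", (12.0, 16.0)),
            ("-8.8 ± 1.3", (-10.1, -7.5)),
            ("> 100", (100.0, 100.0)),
            ("0 ; -7 to -18", (-18.0, 0.0)),
        ],
    )
    def test_cell_grammar(self, cell, expected):
        got = parse_value(cell)
        if expected is None:
            assert got is None
        else:
            assert got == pytest.approx(expected)

    def test_malformed_cell_raises(self):
        with pytest.raises(TableParseError):
            parse_value("twelve-ish")

    def test_round_trip_is_lossless(self, tmp_path):
        records = load_functional_table()
        path = tmp_path / "table.tsv"
        write_functional_table(records, path)
        back = read_functional_table(path)
        assert len(back) == len(records)
        for orig, copy in zip(records, back):
            assert orig.channel == copy.channel
            assert orig.domain == copy.domain
            assert orig.s3_index == copy.s3_index
            assert orig.charge_e0 == copy.charge_e0
            assert orig.q10_act == copy.q10_act
            assert orig.dv12_shift == copy.dv12_shift
            assert orig.mechanosensitive == copy.mechanosensitive


class TestModifiedExponentialFit:
    def test_exact_model_recovery(self):
        x = np.arange(1.0, 7.0)
        a, b, c = 2.0, 1.0, 0.5
        y = a * np.exp(b / (x + c))
        fit = fit_modified_exponential(x, y)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)
        assert (fit.a, fit.b, fit.c) == pytest.approx((a, b, c), abs=1e-6)

    def test_outlier_degrades_r_squared(self):
        x = np.arange(1.0, 7.0)
        y = 2.0 * np.exp(1.0 / (x + 0.5))
        y[3] += 1.5
        fit = fit_modified_exponential(x, y)
        assert fit.r_squared < 1.0

    def test_agrees_with_grid_search_oracle(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([3.1, 2.2, 1.9, 1.7, 1.6])
        fit = fit_modified_exponential(x, y)
        # independent coarse grid search + local polish
        best = math.inf
        for a0 in np.linspace(0.5, 4.0, 12):
            for b0 in np.linspace(-5, 5, 21):
                for c0 in np.linspace(0.1, 8.0, 17):
                    ss = float(np.sum((a0 * np.exp(b0 / (x + c0)) - y) ** 2))
                    if ss < best:
                        best, start = ss, (a0, b0, c0)
        from scipy.optimize import least_squares

        sol = least_squares(
            lambda p: p[0] * np.exp(p[1] / (x + p[2])) - y,
            x0=np.array(start),
            bounds=([1e-12, -np.inf, -0.999999], [np.inf, np.inf, np.inf]),
        )
        assert fit.ss_res <= float(2 * sol.cost) + 1e-4

    def test_c_respects_domain_bound(self):
        x = np.arange(1.0, 10.0)
        y = 1.5 + 0.01 * x
        fit = fit_modified_exponential(x, y)
        assert x.min() + fit.c > 0

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_modified_exponential([1, 2, 3], [1, 2, 3])

    def test_deterministic_given_start(self):
        x = np.arange(1.0, 8.0)
        y = np.array([2.5, 2.0, 1.8, 1.7, 1.65, 1.6, 1.58])
        f1 = fit_modified_exponential(x, y, start=(2.5, 1.0, 1.0))
        f2 = fit_modified_exponential(x, y, start=(2.5, 1.0, 1.0))
        assert (f1.a, f1.b, f1.c, f1.r_squared) == (f2.a, f2.b, f2.c, f2.r_squared)


class TestRankCorrelation:
    def test_perfect_monotone(self):
        pairs = [(i, i ** 2) for i in range(1, 7)]
        rho, p = rank_correlation(pairs)
        assert rho == pytest.approx(1.0)

    def test_reversed_monotone(self):
        pairs = [(i, -i) for i in range(1, 7)]
        rho, _ = rank_correlation(pairs)
        assert rho == pytest.approx(-1.0)

    def test_exact_p_equals_exhaustive_enumeration_n5(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [2.0, 1.0, 4.0, 3.0, 5.0]
        rho, p = rank_correlation(list(zip(x, y)))
        observed = abs(stats.spearmanr(x, y).statistic)
        count = 0
        for perm in itertools.permutations(y):
            r = stats.spearmanr(x, perm).statistic
            count += abs(r) >= observed - 1e-12
        assert p == pytest.approx(count / math.factorial(5))

    def test_invariant_under_monotone_transforms(self):
        pairs = [(1.0, 5.0), (2.0, 3.0), (3.0, 4.0), (4.0, 1.0), (5.0, 2.0)]
        rho1, p1 = rank_correlation(pairs)
        transformed = [(math.exp(x), y ** 3) for x, y in pairs]
        rho2, p2 = rank_correlation(transformed)
        assert rho1 == pytest.approx(rho2)
        assert p1 == pytest.approx(p2)

    def test_montecarlo_path_is_seeded(self):
        rng = np.random.default_rng(7)
        pairs = list(zip(rng.normal(size=12), rng.normal(size=12)))
        r1 = rank_correlation(pairs, n_montecarlo=2000, seed=42)
        r2 = rank_correlation(pairs, n_montecarlo=2000, seed=42)
        assert r1 == r2

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            rank_correlation([(1, 2), (2, 3)])


def assignment_oracle_p(classes, trait):
    """Independent oracle: enumerate which channels carry the trait.

    Under the null every subset of channels of the observed trait count
    is equally likely; the p-value is the fraction of subsets whose
    induced table is at most as probable as the observed one.
    """
    keys = sorted(classes)
    labels = sorted({classes[k] for k in keys})
    n_true = sum(trait[k] for k in keys)

    def table_of(subset):
        return tuple(
            sum(1 for k in subset if classes[k] == lab) for lab in labels
        )

    observed = table_of([k for k in keys if trait[k]])
    counts = {}
    for subset in itertools.combinations(keys, n_true):
        counts[table_of(subset)] = counts.get(table_of(subset), 0) + 1
    total = sum(counts.values())
    p_obs = counts[observed] / total
    return sum(c for t, c in counts.items() if c / total <= p_obs + 1e-12) / total


class TestClassAssociation:
    def _make(self, spec):
        """spec: list of (class, trait) pairs."""
        classes = {f"ch{i}": c for i, (c, _) in enumerate(spec)}
        trait = {f"ch{i}": t for i, (_, t) in enumerate(spec)}
        return classes, trait

    def test_perfect_alignment_minimizes_p(self):
        spec = [("rigid", True)] * 3 + [("flexible", False)] * 3 + [
            ("intermediate", False)
        ] * 3
        classes, trait = self._make(spec)
        result = class_association(classes, trait)
        oracle = assignment_oracle_p(classes, trait)
        assert result.p_value == pytest.approx(oracle)
        assert result.p_value < 0.05

    def test_balanced_independent_trait_gives_p_one(self):
        spec = [
            ("rigid", True), ("rigid", False),
            ("intermediate", True), ("intermediate", False),
            ("flexible", True), ("flexible", False),
        ]
        classes, trait = self._make(spec)
        result = class_association(classes, trait)
        assert result.p_value == pytest.approx(1.0)

    def test_matches_assignment_oracle_on_six_channel_table(self):
        spec = [
            ("rigid", True), ("rigid", True), ("intermediate", False),
            ("intermediate", True), ("flexible", False), ("flexible", False),
        ]
        classes, trait = self._make(spec)
        result = class_association(classes, trait)
        assert result.p_value == pytest.approx(assignment_oracle_p(classes, trait))

    def test_matches_scipy_fisher_on_two_class_table(self):
        spec = [("rigid", True)] * 4 + [("rigid", False)] + [
            ("flexible", True)
        ] + [("flexible", False)] * 4
        classes, trait = self._make(spec)
        result = class_association(classes, trait)
        table = np.array([result.counts[0], result.counts[1]])
        _, expected = stats.fisher_exact(table)
        assert result.p_value == pytest.approx(expected)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            class_association({}, {})
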