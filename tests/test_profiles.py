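import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cidkit.alignment import AMINO_ACIDS, from_sequences
from cidkit.profiles import (
    NOZAKI_TANFORD,
    ColumnProfile,
    ConservationRecord,
    HydropathyRecord,
    ProfileConfig,
    apply_gap_rule,
    bin_conservation,
    classify_position,
    column_counts,
    column_hydropathy,
    conservation_score,
    profile_alignment,
    shannon_entropy,
)

# independently derived: -(20/27 ln(20/27) + 7/27 ln(7/27))
S_Y20_F7 = 0.5722806988018472


def prof(counts, gap_count=0, column=1):
    return ColumnProfile(column=column, counts=counts, gap_count=gap_count)


class TestEntropy:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ({"Y": 27}, 0.0),
            ({"A": 5, "C": 5, "D": 5, "E": 5}, math.log(4)),
            ({"Y": 20, "F": 7}, S_Y20_F7),
        ],
    )
    def test_known_values(self, counts, expected):
        assert shannon_entropy(prof(counts)) == pytest.approx(
            expected, abs=1e-12
        )

    def test_all_gap_column_undefined(self):
        with pytest.raises(ValueError, match="all-gap"):
            shannon_entropy(prof({}, gap_count=5))

    def test_gaps_excluded_from_denominator(self):
        # entropy depends only on the residue composition, not on gaps
        assert shannon_entropy(prof({"Y": 2}, gap_count=2)) == 0.0


class TestConservationScore:
    def test_fully_conserved(self):
        assert conservation_score(0.0, 20) == 1.0

    def test_uniform_over_all_types(self):
        assert conservation_score(math.log(20), 20) == pytest.approx(0.0)

    def test_derived_value(self):
        assert conservation_score(S_Y20_F7, 20) == pytest.approx(
            0.8089680096402869, abs=1e-12
        )

    def test_entropy_above_ln_m_rejected(self):
        with pytest.raises(ValueError):
            conservation_score(math.log(20) + 0.1, 20)

    def test_strictly_decreasing_in_entropy(self):
        scores = [conservation_score(s, 20) for s in np.linspace(0, 2.9, 30)]
        assert all(a > b for a, b in zip(scores, scores[1:]))


class TestGapRule:
    def rec(self, score=0.9, bin="high"):
        return ConservationRecord(
            column=1, entropy=0.1, score=score, m=20, bin=bin
        )

    def test_two_gaps_zeroed(self):
        out = apply_gap_rule(self.rec(), gap_count=2)
        assert out.score == 0.0 and out.bin == "gap_zeroed"

    def test_single_gap_unchanged(self):
        assert apply_gap_rule(self.rec(), gap_count=1) == self.rec()

    def test_no_gap_unchanged(self):
        assert apply_gap_rule(self.rec(), gap_count=0) == self.rec()


class TestBins:
    @pytest.mark.parametrize(
        "score,expected",
        [(0.45, "high"), (0.40, "moderate"), (0.34, "low"),
         (1.0, "high"), (0.35, "moderate"), (0.0, "low")],
    )
    def test_boundaries(self, score, expected):
        assert bin_conservation(score) == expected

    def test_partition(self):
        # every score maps to exactly one bin
        for c in np.linspace(0, 1, 101):
            assert bin_conservation(float(c)) in ("high", "moderate", "low")


class TestHydropathy:
    def test_all_glycine_is_zero(self):
        rec = column_hydropathy(prof({"G": 10}))
        assert rec.hydropathy_sum == 0.0 and rec.hydropathy_mean == 0.0

    @pytest.mark.parametrize("res", list(AMINO_ACIDS))
    def test_single_type_mean_is_scale_value(self, res):
        rec = column_hydropathy(prof({res: 7}))
        assert rec.hydropathy_mean == pytest.approx(
            NOZAKI_TANFORD.values[res]
        )

    def test_mixed_column(self):
        # {I:2, D:1}: (2*1.8 + 0)/3 — hand evaluation
        rec = column_hydropathy(prof({"I": 2, "D": 1}))
        assert rec.hydropathy_mean == pytest.approx(1.2)
        assert rec.hydropathy_sum == pytest.approx(3.6)

    def test_mean_within_scale_range(self):
        rng = np.random.default_rng(0)
        vals = list(NOZAKI_TANFORD.values.values())
        for _ in range(50):
            counts = {
                res: int(c)
                for res, c in zip(
                    AMINO_ACIDS, rng.multinomial(27, [1 / 20] * 20)
                )
                if c > 0
            }
            mean = column_hydropathy(prof(counts)).hydropathy_mean
            assert min(vals) <= mean <= max(vals)


class TestClassify:
    def cons(self, bin="high"):
        return ConservationRecord(
            column=1, entropy=0.0, score=1.0, m=20, bin=bin
        )

    def classify(self, counts, bin="high"):
        p = prof(counts)
        return classify_position(
            self.cons(bin), column_hydropathy(p), p, ProfileConfig()
        )

    def test_mostly_glycine_is_neutral(self):
        assert self.classify({"G": 8, "I": 2}) == "neutral"

    def test_all_isoleucine_is_hydrophobic(self):
        assert self.classify({"I": 27}) == "hydrophobic"

    def test_all_aspartate_is_hydrophilic(self):
        assert self.classify({"D": 27}) == "hydrophilic"

    def test_low_bin_never_classified(self):
        with pytest.raises(ValueError):
            self.classify({"I": 27}, bin="low")

    def test_majority_route(self):
        p = prof({"W": 14, "D": 13})
        cfg = ProfileConfig(classify_by="majority")
        out = classify_position(
            self.cons("high"), column_hydropathy(p), p, cfg
        )
        assert out == "hydrophobic"  # W is the majority type


class TestProfileAlignment:
    def test_identical_sequences_all_high(self):
        aln = from_sequences([(f"s{i}", "ACDEFG") for i in range(5)])
        res = profile_alignment(aln)
        assert all(c.score == 1.0 and c.bin == "high" for c in res.conservation)

    def test_gap_rule_zeroes_everything(self):
        aln = from_sequences(
            [("a", "A-C"), ("b", "--C"), ("c", "A--"), ("d", "-C-")]
        )
        res = profile_alignment(aln)
        assert all(c.score == 0.0 for c in res.conservation)
        assert all(c.bin == "gap_zeroed" for c in res.conservation)

    def test_histogram_counts_all_columns(self):
        aln = from_sequences([(f"s{i}", "ACDEFG") for i in range(5)])
        res = profile_alignment(aln)
        assert sum(res.histogram.values()) == aln.L

    def test_observed_m_single_type_column(self):
        aln = from_sequences([("a", "A"), ("b", "A")])
        res = profile_alignment(aln, ProfileConfig(entropy_m="observed"))
        assert res.conservation[0].score == 1.0

    def test_frame_shape(self, small_alignment):
        df = profile_alignment(small_alignment).to_frame()
        assert list(df.columns) == [
            "column", "n_obs", "gap_count", "entropy_nats", "conservation",
            "bin", "hydropathy_sum", "hydropathy_mean", "phys_class",
        ]
        assert len(df) == small_alignment.L


@st.composite
def random_column(draw):
    n = draw(st.integers(min_value=1, max_value=30))
    residues = draw(
        st.lists(
            st.sampled_from(AMINO_ACIDS), min_size=n, max_size=n
        )
    )
    counts = {}
    for r in residues:
        counts[r] = counts.get(r, 0) + 1
    return counts


class TestProperties:
    @settings(max_examples=100, derandomize=True)
    @given(random_column())
    def test_duplicate_counts_leave_statistics_unchanged(self, counts):
        doubled = {r: 2 * c for r, c in counts.items()}
        assert shannon_entropy(prof(counts)) == pytest.approx(
            shannon_entropy(prof(doubled)), abs=1e-12
        )
        assert column_hydropathy(prof(counts)).hydropathy_mean == pytest.approx(
            column_hydropathy(prof(doubled)).hydropathy_mean, abs=1e-12
        )

    @settings(max_examples=50, derandomize=True)
    @given(random_column())
    def test_entropy_invariant_under_relabeling(self, counts):
        # permute which amino acid holds which count
        values = sorted(counts.values(), reverse=True)
        relabeled = dict(zip(AMINO_ACIDS, values))
        relabeled = {r: c for r, c in relabeled.items() if c > 0}
        assert shannon_entropy(prof(counts)) == pytest.approx(
            shannon_entropy(prof(relabeled)), abs=1e-12
        )

    def test_brute_force_oracle_random_alignment(self):
        rng = np.random.default_rng(42)
        rows = [
            "".join(rng.choice(list(AMINO_ACIDS), size=30))
            for _ in range(10)
        ]
        aln = from_sequences([(f"s{i}", row) for i, row in enumerate(rows)])
        res = profile_alignment(aln)
        for col in range(1, 31):
            chars = aln.column(col)
            naive = 0.0
            for r in set(chars):
                p = chars.count(r) / len(chars)
                naive -= p * math.log(p)
            assert res.conservation[col - 1].entropy == pytest.approx(
                naive, abs=1e-12
            )

    def test_sequence_order_invariance(self, small_alignment):
        reversed_aln = from_sequences(
            [
                (r.seq_id, r.residues)
                for r in reversed(small_alignment.records)
            ]
        )
        a = profile_alignment(small_alignment)
        b = profile_alignment(reversed_aln)
        assert [c.score for c in a.conservation] == [
            c.score for c in b.conservation
        ]
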