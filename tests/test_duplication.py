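import itertools
import warnings

import pytest
from Bio.Seq import Seq
from hypothesis import given, settings
from hypothesis import strategies as st

from glyfam.duplication import (
    CodonAlignment,
    SENSE_CODONS,
    classify_duplication,
    codon_align,
    codon_pair_differences,
    codon_site_fractions,
    divergence_time,
    ng86,
    ng86_counts,
    pairwise_identity,
    selection_class,
)
from glyfam.fixtures import load_pair_table

# ---------------------------------------------------------------------------
# Independent brute-force oracle: recursion + Biopython translation, no
# shared code with the implementation's table-driven counting.


def _aa(codon: str) -> str:
    return str(Seq(codon).translate())


def oracle_site_count(codon: str) -> float:
    s = 0.0
    for pos in range(3):
        syn = valid = 0
        for b in "ACGT":
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if _aa(alt) == "*":
                continue
            valid += 1
            if _aa(alt) == _aa(codon):
                syn += 1
        if valid:
            s += syn / valid
    return s


def oracle_differences(ca: str, cb: str):
    paths = []

    def rec(cur, remaining, syn, nonsyn):
        if not remaining:
            paths.append((syn, nonsyn))
            return
        for pos in remaining:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
            if _aa(nxt) == "*":
                continue
            step_syn = _aa(cur) == _aa(nxt)
            rec(
                nxt,
                [p for p in remaining if p != pos],
                syn + step_syn,
                nonsyn + (not step_syn),
            )

    rec(ca, [i for i in range(3) if ca[i] != cb[i]], 0, 0)
    if not paths:
        return None
    n = len(paths)
    return (sum(p[0] for p in paths) / n, sum(p[1] for p in paths) / n)


class TestNg86Oracle:
    def test_single_codon_spec_example(self):
        counts = ng86_counts(CodonAlignment(["TTT"], ["TTA"]))
        assert counts.S == pytest.approx(0.5)
        assert counts.N == pytest.approx(2.5)
        assert (counts.Sd, counts.Nd) == (0.0, 1.0)

    def test_site_counts_all_codons(self):
        for codon in SENSE_CODONS:
            assert codon_site_fractions(codon) == pytest.approx(
                oracle_site_count(codon), abs=1e-12
            ), codon

    def test_pathway_differences_all_pairs(self):
        """Pathway averaging equals brute-force enumeration for every
        sense-codon pair (including 2- and 3-position differences)."""
        for ca, cb in itertools.product(SENSE_CODONS, repeat=2):
            got = codon_pair_differences(ca, cb)
            want = oracle_differences(ca, cb)
            if want is None:
                assert got[0] != got[0]  # NaN: all pathways blocked
            else:
                assert got[0] == pytest.approx(want[0], abs=1e-12), (ca, cb)
                assert got[1] == pytest.approx(want[1], abs=1e-12), (ca, cb)

    def test_identical_sequences_zero(self):
        cods = ["ATG", "AAA", "TTT"]
        counts, ka, ks = ng86(CodonAlignment(cods, cods))
        assert (counts.Sd, counts.Nd, ka, ks) == (0, 0, 0, 0)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        a=st.lists(st.sampled_from(SENSE_CODONS), min_size=2, max_size=8),
        b=st.lists(st.sampled_from(SENSE_CODONS), min_size=2, max_size=8),
    )
    def test_symmetry_and_site_total(self, a, b):
        n = min(len(a), len(b))
        a, b = a[:n], b[:n]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            c1 = ng86_counts(CodonAlignment(a, b))
            c2 = ng86_counts(CodonAlignment(b, a))
        assert c1.S == pytest.approx(c2.S, abs=1e-12)
        assert c1.Sd == pytest.approx(c2.Sd, abs=1e-12)
        assert c1.Nd == pytest.approx(c2.Nd, abs=1e-12)
        # S + N = 3 x n unless a codon column was dropped (blocked paths)
        dropped = sum(
            1 for ca, cb in zip(a, b)
            if codon_pair_differences(ca, cb)[0] != codon_pair_differences(ca, cb)[0]
        )
        assert c1.S + c1.N == pytest.approx(3 * (n - dropped), abs=1e-9)

    def test_saturation_errors(self):
        with pytest.raises(ValueError, match="saturat"):
            ng86(CodonAlignment(["AAA"] * 10, ["GGC"] * 10))


class TestCodonAlign:
    def test_identical(self):
        cds = "ATGAAATTTGGGCCCAAAGATTGTCTGTAA"
        aln = codon_align(cds, cds)
        assert aln.n_codons == 9 and aln.dropped_columns == 0

    def test_insertion_column_dropped(self):
        a = "ATGAAATTTGGGCCC"
        b = "ATGAAAGACTTTGGGCCC"  # one extra codon
        aln = codon_align(a, b)
        assert aln.n_codons == 5
        assert aln.dropped_columns == 1

    def test_ambiguous_codon_dropped(self):
        a = "ATGAAATTT"
        b = "ATGNNNTTT"
        aln = codon_align(a, b)
        assert aln.n_codons == 2 and aln.dropped_columns == 1

    def test_non_triplet_errors(self):
        with pytest.raises(ValueError):
            codon_align("ATGA", "ATGAAA")


class TestIdentityAndTyping:
    def test_identical_sequences(self):
        assert pairwise_identity("MKV" * 30, "MKV" * 30) == 100.0

    def test_one_substitution_in_ten(self):
        a = "MKVLSAFGDR"
        b = "MKVLSAFGDW"
        assert pairwise_identity(a, b) == pytest.approx(90.0)

    def test_unrelated_sequences_low(self):
        import numpy as np

        rng = np.random.default_rng(0)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        vals = []
        for _ in range(5):
            a = "".join(rng.choice(aas, 50))
            b = "".join(rng.choice(aas, 50))
            vals.append(pairwise_identity(a, b))
        assert sum(vals) / len(vals) < 40

    @pytest.mark.parametrize(
        "same_chrom,ident,ngenes,gap,expected",
        [
            (True, 95.0, 0, 4000, "tandem"),
            (False, 95.0, 10**9, 10**9, "segmental"),
            (True, 85.0, 0, 1000, "none"),
            (True, 95.0, 6, 4000, "segmental"),   # too many intervening
            (True, 95.0, 2, 150_000, "segmental"),  # too far apart
        ],
    )
    def test_classify_duplication(self, same_chrom, ident, ngenes, gap,
                                  expected):
        assert classify_duplication(same_chrom, ident, ngenes, gap) == expected


class TestDivergenceAndSelection:
    def test_printed_pairs_reproduced(self):
        """Every printed Ks maps to the printed time and every printed
        (Ka, Ks) to the printed ratio, at 4 decimal places (15/15)."""
        df = load_pair_table()
        for row in df.itertuples():
            assert round(divergence_time(row.ks), 4) == pytest.approx(
                row.time_mya
            ), row.locus1
            assert round(row.ka / row.ks, 4) == pytest.approx(
                row.ka_ks
            ), row.locus1

    def test_example_values(self):
        assert divergence_time(0.1246) == pytest.approx(10.2131, abs=5e-5)
        assert divergence_time(0.4137) == pytest.approx(33.9098, abs=5e-5)
        assert divergence_time(0.0) == 0.0

    def test_negative_ks_errors(self):
        with pytest.raises(ValueError):
            divergence_time(-0.1)

    @pytest.mark.parametrize(
        "ka,ks,expected",
        [
            (0.0354, 0.1246, "purifying"),
            (0.1, 0.1, "neutral"),
            (0.2, 0.1, "positive"),
        ],
    )
    def test_selection_class(self, ka, ks, expected):
        assert selection_class(ka, ks) == expected

    def test_zero_ks_positive_with_warning(self):
        with pytest.warns(UserWarning):
            assert selection_class(0.1, 0.0) == "positive"
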