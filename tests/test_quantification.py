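"""MNI formulas against a minimal-individual packing oracle, apportionment,
abundance and diversity."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from shellseasons import quantification as q


def _bivalve(left, right, unsided=0):
    keys = ("COMV", "FRAV", "FCH", "AHF", "PHF")
    return q.FragmentCounts(
        unit_id="u", taxon="Mytilus", taxon_class="bivalve",
        left=dict(zip(keys, left)), right=dict(zip(keys, right)), unsided=unsided,
    )


def _spiralled(**counts):
    return q.FragmentCounts(unit_id="u", taxon="Phorcus",
                            taxon_class="spiralled_gastropod", counts=counts)


def _non_spiralled(**counts):
    return q.FragmentCounts(unit_id="u", taxon="Patella",
                            taxon_class="non_spiralled_gastropod", counts=counts)


def minimal_individuals_oracle(fc: q.FragmentCounts) -> int:
    """Enumerate the fewest individuals that can supply the tallied elements.

    Complete/fragmented individuals (COMV, FRAV, FCH, COMI, FRAI) each stand
    for one animal with its diagnostic elements intact.  Every further animal
    can shed at most one of each loose diagnostic element: one apex and one
    base fragment (stoma OR umbilical - the base is one region) for
    gastropods; one anterior and one posterior hinge fragment per valve for
    bivalves.  Undiagnostic fragments constrain nothing.
    """

    def smallest_k(*loose_requirements):
        k = 0
        while any(k < need for need in loose_requirements):
            k += 1
        return k

    if fc.taxon_class == "bivalve":
        totals = []
        for side in (fc.left, fc.right):
            g = lambda c: side.get(c, 0)
            whole = g("COMV") + g("FRAV") + g("FCH")
            totals.append(whole + smallest_k(g("AHF"), g("PHF")))
        return max(totals)
    g = lambda c: fc.counts.get(c, 0)
    whole = g("COMI") + g("FRAI")
    if fc.taxon_class == "spiralled_gastropod":
        return whole + smallest_k(g("APIF"), g("STOF") + g("UMBF"))
    return whole + smallest_k(g("APIF"))


class TestMNIFormulas:
    def test_bivalve_example(self):
        fc = _bivalve(left=(2, 1, 0, 3, 1), right=(1, 0, 1, 2, 4))
        assert q.mni_bivalve(fc) == 6  # max(2+1+0+3, 1+0+1+4)

    def test_bivalve_symmetric_sides(self):
        fc = _bivalve(left=(2, 1, 1, 0, 2), right=(2, 1, 1, 0, 2))
        assert q.mni_bivalve(fc) == 6

    def test_spiralled_example(self):
        fc = _spiralled(COMI=5, FRAI=2, APIF=4, STOF=3, UMBF=2)
        assert q.mni_spiralled(fc) == 12  # 5 + 2 + max(4, 5)

    def test_fts_never_counted(self):
        base = _spiralled(COMI=5, FRAI=2, APIF=4, STOF=3, UMBF=2)
        loaded = _spiralled(COMI=5, FRAI=2, APIF=4, STOF=3, UMBF=2, FTS=1000)
        assert q.mni_spiralled(base) == q.mni_spiralled(loaded)

    def test_non_spiralled_example(self):
        assert q.mni_non_spiralled(_non_spiralled(COMI=3, FRAI=2, APIF=4)) == 9
        assert q.mni_non_spiralled(_non_spiralled(COMI=3, FRAI=2, APIF=4, FTS=50)) == 9

    @pytest.mark.parametrize("maker", [_bivalve, _spiralled, _non_spiralled])
    def test_all_zero_counts(self, maker):
        fc = maker() if maker is not _bivalve else _bivalve((0,) * 5, (0,) * 5)
        assert q.mni(fc) == 0

    def test_wrong_class_rejected(self):
        with pytest.raises(ValueError):
            q.mni_bivalve(_spiralled(COMI=1))
        with pytest.raises(ValueError):
            q.mni_spiralled(_non_spiralled(COMI=1))
        with pytest.raises(ValueError):
            q.mni_non_spiralled(_spiralled(COMI=1))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            _spiralled(COMI=-1)

    def test_formulas_match_packing_oracle(self):
        """500 random small count vectors across all three taxon classes."""
        rng = np.random.default_rng(42)
        for _ in range(500):
            kind = rng.integers(3)
            if kind == 0:
                fc = _bivalve(rng.integers(0, 11, 5), rng.integers(0, 11, 5),
                              unsided=int(rng.integers(0, 11)))
            elif kind == 1:
                fc = _spiralled(**{c: int(rng.integers(0, 11))
                                   for c in q.SPIRALLED_CATEGORIES})
            else:
                fc = _non_spiralled(**{c: int(rng.integers(0, 11))
                                       for c in q.NON_SPIRALLED_CATEGORIES})
            assert q.mni(fc) == minimal_individuals_oracle(fc)


def largest_remainder_oracle(shares, total):
    """Exact-fraction largest-remainder allocation (independent arithmetic)."""
    s = sum(shares.values())
    quotas = {k: Fraction(total * v, s) for k, v in shares.items()}
    alloc = {k: int(quota) for k, quota in quotas.items()}
    rest = total - sum(alloc.values())
    by_rem = sorted(shares, key=lambda k: (-(quotas[k] - alloc[k]), -shares[k], k))
    for k in by_rem[:rest]:
        alloc[k] += 1
    return alloc


class TestApportionment:
    def test_sixty_forty_example(self):
        assert q.apportion_indeterminate({"A": 60, "B": 40}, 10) == {"A": 66, "B": 44}

    def test_zero_indeterminate_unchanged(self):
        assert q.apportion_indeterminate({"A": 50, "B": 50}, 0) == {"A": 50, "B": 50}

    def test_no_identified_individuals_rejected(self):
        with pytest.raises(ValueError):
            q.apportion_indeterminate({"A": 0}, 5)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            q.apportion_indeterminate({"A": 10}, -1)

    def test_conservation_and_oracle_on_random_cases(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            n_sp = int(rng.integers(1, 6))
            shares = {f"sp{i}": int(rng.integers(0, 50)) for i in range(n_sp)}
            if sum(shares.values()) == 0:
                shares["sp0"] = 1
            indet = int(rng.integers(0, 30))
            result = q.apportion_indeterminate(shares, indet)
            assert sum(result.values()) == sum(shares.values()) + indet
            oracle = largest_remainder_oracle(shares, indet)
            assert result == {k: shares[k] + oracle[k] for k in shares}

    @given(st.dictionaries(st.sampled_from("ABCDE"), st.integers(0, 99),
                           min_size=1, max_size=5),
           st.integers(0, 99))
    @settings(derandomize=True, max_examples=60)
    def test_permutation_equivariance(self, shares, indet):
        if sum(shares.values()) == 0:
            shares[next(iter(shares))] = 1
        renamed = {k.lower(): v for k, v in shares.items()}
        out = q.apportion_indeterminate(shares, indet)
        out_renamed = q.apportion_indeterminate(renamed, indet)
        assert {k.lower(): v for k, v in out.items()} == out_renamed


class TestAbundanceAndDiversity:
    def test_relative_abundance(self):
        assert q.relative_abundance({"A": 3, "B": 1}) == {"A": 0.75, "B": 0.25}
        assert q.relative_abundance({"A": 5}) == {"A": 1.0}

    def test_abundance_sums_to_one(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            table = {f"t{i}": int(n) for i, n in enumerate(rng.integers(0, 100, 6))}
            if sum(table.values()) == 0:
                table["t0"] = 1
            assert sum(q.relative_abundance(table).values()) == pytest.approx(1.0)

    def test_empty_unit_rejected(self):
        with pytest.raises(ValueError):
            q.relative_abundance({})

    def test_simpson_single_taxon(self):
        assert q.simpson_index({"A": 7}) == pytest.approx(1.0)

    def test_simpson_two_equal_taxa(self):
        assert q.simpson_index({"A": 10, "B": 10}) == pytest.approx(0.5)

    @given(st.dictionaries(st.sampled_from("ABCDEF"), st.integers(0, 99),
                           min_size=1, max_size=6))
    @settings(derandomize=True, max_examples=60)
    def test_variants_are_complementary(self, table):
        if sum(table.values()) == 0:
            table[next(iter(table))] = 1
        d = q.simpson_index(table, "dominance")
        assert d + q.simpson_index(table, "diversity") == pytest.approx(1.0)
        assert 0.0 <= d <= 1.0
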