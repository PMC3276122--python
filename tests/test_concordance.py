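"""Concordance classification and the exact chance-probability model.

The closed-form configuration probability is checked against an exhaustive
enumeration oracle that sums, over every joint marker-genotype/phase outcome
of the independent sires under the null, the probability of the outcomes
producing the target configuration.
"""

import itertools
import math

import numpy as np
import pytest

from qtnmap import (Classification, classify_snp, concordance_chance_probability,
                    configuration_probability, expected_concordant_count,
                    scan_concordance, tail_probability, MISSING,
                    PhaseAssignment, QtlStatus, SirePanel, SnpInfo)
from qtnmap.concordance import results_to_frame
from qtnmap.errors import DomainError, ValidationError
from qtnmap.simulate import SimulationConfig, simulate_panel


def enumeration_oracle(n_hom, n_het, target, p):
    """Exhaustive null enumeration of per-sire marker genotype/phase outcomes.

    A QTL-homozygous sire's marker genotype is homozygous (p^2 + q^2) or
    heterozygous (2pq); a QTL-heterozygous sire is marker-homozygous, or
    heterozygous with the designated linked allele (pq), or heterozygous
    with the other allele (pq).  Sums the probability of every joint outcome
    whose (n_hom_match, n_het_match, k) equals ``target``.
    """
    q = 1.0 - p
    hom_out = [("match", p * p + q * q), ("miss", 2 * p * q)]
    het_out = [("hom", p * p + q * q), ("het_correct", p * q), ("het_other", p * q)]
    total = 0.0
    for hc in itertools.product(hom_out, repeat=n_hom):
        for tc in itertools.product(het_out, repeat=n_het):
            cfg = (sum(o == "match" for o, _ in hc),
                   sum(o != "hom" for o, _ in tc),
                   sum(o == "het_correct" for o, _ in tc))
            if cfg == target:
                total += math.prod(w for _, w in hc) * math.prod(w for _, w in tc)
    return total


@pytest.mark.parametrize("n_hom", [0, 1, 2, 3])
@pytest.mark.parametrize("n_het", [0, 1, 2, 3])
@pytest.mark.parametrize("p", [0.1, 0.5, 0.7])
def test_configuration_probability_matches_enumeration(n_hom, n_het, p):
    for n_hom_match in range(n_hom + 1):
        for n_het_match in range(n_het + 1):
            for k in range(n_het_match + 1):
                closed = configuration_probability(
                    n_hom, n_het, n_hom_match, n_het_match, k, p)
                brute = enumeration_oracle(
                    n_hom, n_het, (n_hom_match, n_het_match, k), p)
                assert closed == pytest.approx(brute, abs=1e-12)


def test_chance_probability_published_configuration():
    """5 hom/hom, 5 het/het, 4 of 5 sharing one phase at p = 0.5."""
    p = concordance_chance_probability(5, 5, 4, 0.5)
    assert p == pytest.approx(0.0001525879, abs=1e-10)
    assert float(f"{p:.3g}") == pytest.approx(0.000153)  # 0.000152 before rounding


def test_chance_probability_trivial_and_derived():
    assert concordance_chance_probability(0, 0, 0, 0.3) == 1.0
    # (p^2+q^2)^2 * C(2,2) * (pq)^2 at p = 0.3
    assert concordance_chance_probability(2, 2, 2, 0.3) == \
        pytest.approx(0.01483524, abs=1e-12)


def test_chance_probability_domain_errors():
    with pytest.raises(DomainError):
        concordance_chance_probability(5, 5, 4, 0.0)
    with pytest.raises(DomainError):
        concordance_chance_probability(5, 5, 6, 0.5)  # k > n_het


def test_probability_symmetric_in_p():
    for args in [(5, 5, 4), (3, 2, 1), (0, 4, 2)]:
        assert concordance_chance_probability(*args, 0.3) == \
            pytest.approx(concordance_chance_probability(*args, 0.7), rel=1e-15)


def test_unanimous_phase_not_above_max_over_k():
    probs = [concordance_chance_probability(5, 5, k, 0.4) for k in range(6)]
    assert probs[5] <= max(probs)


def test_full_null_distribution_normalizes():
    for n_hom, n_het, p in [(3, 3, 0.3), (5, 5, 0.5), (2, 4, 0.17)]:
        total = sum(
            configuration_probability(n_hom, n_het, hm, tm, k, p)
            for hm in range(n_hom + 1)
            for tm in range(n_het + 1)
            for k in range(tm + 1)
        )
        assert total == pytest.approx(1.0, abs=1e-12)


def test_expected_concordant_count():
    assert expected_concordant_count(0.0001525879, 704) == \
        pytest.approx(0.1074, abs=5e-4)
    assert expected_concordant_count(0.0, 10**6) == 0.0
    assert expected_concordant_count(0.01, 50) == pytest.approx(0.5)
    with pytest.raises(DomainError):
        expected_concordant_count(1.5, 10)


class TestClassifySnp:
    def test_published_panel_is_phase_partial(self, panel, phases):
        """5/5 state matches on both sides, 4 of 5 phase-correct: nine of the
        ten families are concordant."""
        res = classify_snp(panel, "NGS-58779", phases, null_p=0.5)
        c = res.config
        assert (c.n_hom_match, c.n_het_match, c.k_phase_correct) == (5, 5, 4)
        assert res.classification is Classification.PHASE_PARTIAL
        assert res.n_concordant_families == 9
        assert res.chance_probability == pytest.approx(0.0001525879, abs=1e-10)

    def test_panel_estimated_frequency_used_without_override(self, panel, phases):
        res = classify_snp(panel, "NGS-58779", phases)
        assert res.config.p == pytest.approx(0.45)

    def test_all_homozygous_no_phases_is_full(self):
        snp = SnpInfo("s", "7", 100, ("A", "G"))
        panel = SirePanel([f"x{i}" for i in range(10)], [QtlStatus.HOM] * 10,
                          np.array([[2]] * 5 + [[0]] * 5), [snp])
        res = classify_snp(panel, "s", null_p=0.5)
        assert res.classification is Classification.FULL
        assert res.config.k_phase_correct == 0

    def test_missing_genotype_skips(self, panel):
        geno = panel.genotypes.copy()
        geno[0, 0] = MISSING
        p2 = SirePanel(panel.sire_ids, panel.qtl_status, geno, panel.snps)
        res = classify_snp(p2, "NGS-58779")
        assert res.classification is Classification.SKIPPED_MISSING
        assert res.chance_probability is None

    def test_phase_for_marker_homozygote_rejected(self, panel):
        with pytest.raises(ValidationError):
            classify_snp(panel, "NGS-58779", [PhaseAssignment("3099", "A")])

    def test_phase_tie_takes_ceiling_and_flags(self):
        snp = SnpInfo("s", "7", 100, ("A", "G"))
        panel = SirePanel(["a", "b", "c", "d"], [QtlStatus.HET] * 4,
                          np.array([[1]] * 4), [snp])
        res = classify_snp(panel, "s",
                           [PhaseAssignment("a", "A"), PhaseAssignment("b", "A"),
                            PhaseAssignment("c", "G"), PhaseAssignment("d", "G")],
                           null_p=0.5)
        assert res.phase_tie
        assert res.config.k_phase_correct == 2
        assert res.classification is Classification.PHASE_PARTIAL


class TestScan:
    def test_qtn_linked_snp_ranks_first(self):
        """A SNP column in complete LD with the QTN classifies FULL and
        outranks every unlinked marker; the ranking agrees with per-SNP
        brute-force classification."""
        cfg = SimulationConfig(n_snps=30, qtn_index=15, seed=11,
                               n_founder_haplotypes=2, n_ancestral=2,
                               mutation_rate=0.0, ld_block_length_bp=1e12)
        panel, _w, phases, _t = simulate_panel(cfg)
        results = scan_concordance(panel, phases)
        # complete LD: the QTN's own column must be fully concordant
        by_id = {r.snp_id: r for r in results}
        assert by_id["qtn"].classification is Classification.FULL
        assert results[0].classification is Classification.FULL
        ranks = [(r.snp_id, r.classification) for r in results]
        brute = [(s.snp_id, classify_snp(panel, s.snp_id, phases.get(s.snp_id)).classification)
                 for s in panel.snps]
        assert dict(brute) == {s: c for s, c in ranks}

    def test_empty_region_gives_empty_list(self, panel):
        assert scan_concordance(panel, region=(0, 10)) == []

    def test_ranking_is_deterministic(self, panel, phases):
        a = scan_concordance(panel, {"NGS-58779": phases}, null_p=0.5)
        b = scan_concordance(panel, {"NGS-58779": phases}, null_p=0.5)
        assert [r.snp_id for r in a] == [r.snp_id for r in b]
        df = results_to_frame(a)
        assert list(df.columns)[:2] == ["snp_id", "position_bp"]
        assert df["rank"].tolist() == [1]


def test_tail_probability_sums_configurations():
    t = tail_probability(5, 5, 4, 0.5)
    expect = (concordance_chance_probability(5, 5, 4, 0.5)
              + concordance_chance_probability(5, 5, 5, 0.5))
    assert t == pytest.approx(expect, rel=1e-15)
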