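"""Codon site counting, NG86 divergence and Cliff's delta."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from Bio.Data import CodonTable

from paralog_fates.seqdiv import (
    STANDARD_CODE,
    cliffs_delta,
    count_codon_sites,
    ng86_divergence,
    pairwise_dn_table,
    per_gene_omega,
)
from paralog_fates.synth import simulate_codon_pairs, simulate_family_codon_set

TABLE = CodonTable.unambiguous_dna_by_id[1]
CODE = dict(TABLE.forward_table, **{c: "*" for c in TABLE.stop_codons})
SENSE = sorted(c for c, aa in CODE.items() if aa != "*")


def neighbor_syn_fraction(codon: str) -> float:
    """Independent oracle: enumerate all 9 single-base neighbors."""
    syn = 0.0
    for pos, alt in itertools.product(range(3), "TCAG"):
        if alt == codon[pos]:
            continue
        neighbor = codon[:pos] + alt + codon[pos + 1 :]
        if CODE[neighbor] == CODE[codon]:  # stops differ from any amino acid
            syn += 1 / 3
    return syn


@pytest.mark.parametrize("codon,expected_syn", [("TTT", 1 / 3), ("GTT", 1.0), ("ATG", 0.0)])
def test_site_counts_worked_codons(codon, expected_syn):
    syn, nonsyn = count_codon_sites(codon)
    assert syn == pytest.approx(expected_syn)
    assert syn + nonsyn == pytest.approx(3.0)


def test_site_counts_match_neighbor_enumeration_for_all_sense_codons():
    for codon in SENSE:
        syn, nonsyn = count_codon_sites(codon)
        assert syn == pytest.approx(neighbor_syn_fraction(codon)), codon
        assert syn + nonsyn == pytest.approx(3.0), codon


def test_site_counts_reject_stop_and_ambiguous():
    with pytest.raises(ValueError):
        count_codon_sites("TAA")
    with pytest.raises(ValueError):
        count_codon_sites("ANT")


def test_single_codon_pair_hand_case():
    """TTT vs GTT: one non-synonymous difference, hand-evaluated NG86."""
    est = ng86_divergence("TTT", "GTT")
    assert est.Nd == pytest.approx(1.0)
    assert est.Sd == pytest.approx(0.0)
    assert est.N_sites == pytest.approx(7 / 3)
    assert est.S_sites == pytest.approx(2 / 3)
    assert est.pN == pytest.approx(3 / 7)
    assert est.dN == pytest.approx(-0.75 * np.log(1 - 4 / 3 * 3 / 7))
    assert est.dN == pytest.approx(0.635, abs=5e-4)
    assert est.dS == pytest.approx(0.0)
    assert est.omega is None


def test_identical_sequences_zero_divergence():
    seq = "ATGGTTCCTAAA"
    est = ng86_divergence(seq, seq)
    assert est.Nd == est.Sd == 0
    assert est.dN == est.dS == 0
    assert est.omega is None  # dS = 0


def test_sites_conservation_and_symmetry(rng):
    for _ in range(20):
        a = "".join(rng.choice(SENSE, 30))
        b = "".join(rng.choice(SENSE, 30))
        e1, e2 = ng86_divergence(a, b), ng86_divergence(b, a)
        assert e1.S_sites + e1.N_sites == pytest.approx(3 * e1.n_codons_compared)
        assert e1.Nd == pytest.approx(e2.Nd)
        assert e1.Sd == pytest.approx(e2.Sd)
        assert (e1.dN is None) == (e2.dN is None)
        if e1.dN is not None:
            assert e1.dN == pytest.approx(e2.dN)


def test_gapped_and_ambiguous_codons_skipped_pairwise():
    # middle codon gapped in one sequence, last codon ambiguous in the other:
    # only the first codon remains comparable
    est = ng86_divergence("TTT---GTT", "TTTAAANTT")
    assert est.n_codons_compared == 1
    est2 = ng86_divergence("TTTAAAGTT", "TTT---GTT")
    assert est2.n_codons_compared == 2


def test_no_comparable_codons_rejected():
    with pytest.raises(ValueError):
        ng86_divergence("---", "TTT")


def test_saturation_flagged():
    # force pN towards 1 with maximally different codons repeated
    est = ng86_divergence("ATG" * 50, "TGG" * 50)
    if est.pN >= 0.75:
        assert est.dN is None and "dN_saturated" in est.flags


def test_dn_negligible_when_simulated_omega_zero():
    """Pure-synonymous evolution: dN is zero up to pathway-averaging noise.

    When two synonymous hits land in the same codon, NG86 averages over
    substitution orders and may route through a non-synonymous
    intermediate, so dN is bounded near zero rather than exactly zero;
    codons differing at a single position must all be synonymous.
    """
    from Bio.Seq import Seq

    pairs, _ = simulate_codon_pairs(300, 0.0, 0.3, 5, seed=21)
    for a, b in pairs:
        est = ng86_divergence(a, b)
        assert est.dS > 0
        assert est.dN < 0.01 and est.dN < 0.05 * est.dS
        for i in range(0, len(a), 3):
            ca, cb = a[i : i + 3], b[i : i + 3]
            if sum(x != y for x, y in zip(ca, cb)) == 1:
                assert Seq(ca).translate() == Seq(cb).translate()


def test_dn_increases_with_divergence_time():
    def mean_dn(t, seed):
        pairs, _ = simulate_codon_pairs(400, 0.5, t, 10, seed=seed)
        return np.mean([ng86_divergence(a, b).dN for a, b in pairs])

    assert mean_dn(0.1, 31) < mean_dn(0.3, 32) < mean_dn(0.7, 33)


# -- per-gene omega ----------------------------------------------------


def test_per_gene_omega_identical_pair_undefined():
    est = per_gene_omega(["ATGGTT", "ATGGTT"])
    assert est.omega is None


def test_per_gene_omega_recovery_and_ordering():
    """Counting estimator recovers the generating omega on small clades."""
    from paralog_fates.synth import simulate_codon_clade

    errs, order_ok = [], 0
    n_rep = 5
    for rep in range(n_rep):
        ests = {}
        for omega in (0.05, 0.5):
            _, seqs, _ = simulate_codon_clade(800, omega, 0.45, 8, seed=500 + 7 * rep + int(omega * 100))
            ests[omega] = per_gene_omega([STANDARD_CODE.encode(s) for s in seqs]).omega
            errs.append(abs(ests[omega] - omega))
        order_ok += ests[0.05] < ests[0.5]
    assert np.mean(errs) < 0.05
    assert order_ok == n_rep


# -- pairwise dN table -------------------------------------------------


def _family_fixture(seed=77):
    return simulate_family_codon_set(
        n_codons=200, expected_subs_per_codon=0.3, omega_pre=0.2,
        omega_a=0.05, omega_b=0.5,
        pre_species=["pre1", "pre2"], post_species=["post1", "post2", "post3"],
        seed=seed, family="fam",
    )


def test_dn_table_row_count():
    seqs, rows = _family_fixture()
    import pandas as pd

    table = pairwise_dn_table({"fam": seqs}, pd.DataFrame(rows))
    # 2 pre-species x 3 post-species x 2 paralogs
    assert len(table) == 12
    assert (table["dN"] >= 0).all()


def test_dn_table_length_filter_excludes_short_sequences():
    import pandas as pd

    seqs, rows = _family_fixture()
    short_id = "fam.post1.A"
    seqs = dict(seqs)
    seqs[short_id] = seqs[short_id][: 3 * 60]  # 0.3 of the 200-codon reference
    table = pairwise_dn_table({"fam": seqs}, pd.DataFrame(rows), min_length_frac=0.5)
    assert short_id not in set(table["post_seq"])
    assert len(table) == 10


def test_dn_table_family_without_pre_sequences_skipped():
    import pandas as pd

    seqs, rows = _family_fixture()
    rows = [r for r in rows if r["role"] == "post"]
    table = pairwise_dn_table({"fam": seqs}, pd.DataFrame(rows))
    assert table.empty


def test_dn_table_detects_asymmetric_paralog_divergence():
    """Fast-evolving paralog B shows higher median dN than conserved A."""
    import pandas as pd

    tables = []
    for rep in range(10):
        seqs, rows = simulate_family_codon_set(
            n_codons=300, expected_subs_per_codon=0.3, omega_pre=0.2,
            omega_a=0.05, omega_b=0.5,
            pre_species=["pre1"], post_species=["post1", "post2"],
            seed=900 + rep, family=f"fam{rep}",
        )
        tables.append(pairwise_dn_table({f"fam{rep}": seqs}, pd.DataFrame(rows)))
    table = pd.concat(tables)
    med = table.groupby("paralog")["dN"].median()
    assert med["B"] > med["A"]


def test_omega_negatively_correlates_with_expression_by_construction():
    """Highly expressed genes evolve under stronger constraint (lower omega)."""
    from scipy.stats import spearmanr

    from paralog_fates.synth import simulate_codon_clade

    # gene i simulated with high expression <-> low omega
    omegas = [0.05, 0.1, 0.2, 0.35, 0.5]
    median_expr = [9.0, 7.5, 5.0, 3.0, 1.5]  # log2 scale, anti-ordered
    ests = []
    for i, om in enumerate(omegas):
        _, seqs, _ = simulate_codon_clade(600, om, 0.45, 6, seed=40 + i)
        ests.append(per_gene_omega([STANDARD_CODE.encode(s) for s in seqs]).omega)
    rho = spearmanr(median_expr, ests).statistic
    assert rho < -0.8


# -- Cliff's delta -----------------------------------------------------


def brute_force_delta(a, b):
    gt = sum(1 for x in a for y in b if x > y)
    lt = sum(1 for x in a for y in b if x < y)
    return (gt - lt) / (len(a) * len(b))


def test_cliffs_delta_worked_example():
    d = cliffs_delta([1, 2], [2, 3])
    assert d.delta_signed == pytest.approx(-0.75)
    assert d.delta_magnitude == pytest.approx(0.75)
    assert d.delta_magnitude == pytest.approx(brute_force_delta([1, 2], [2, 3]) * -1)


def test_cliffs_delta_identical_and_separated_groups():
    assert cliffs_delta([1, 2, 3], [1, 2, 3]).delta_signed == 0
    assert cliffs_delta([1, 2], [5, 6]).delta_magnitude == 1
    assert cliffs_delta([5, 6], [1, 2]).is_large


def test_cliffs_delta_rejects_empty_group():
    with pytest.raises(ValueError):
        cliffs_delta([], [1.0])


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    a=st.lists(st.floats(-50, 50).map(lambda x: round(x, 3)), min_size=1, max_size=12),
    b=st.lists(st.floats(-50, 50).map(lambda x: round(x, 3)), min_size=1, max_size=12),
)
def test_cliffs_delta_matches_enumeration_and_antisymmetry(a, b):
    d = cliffs_delta(a, b)
    assert d.delta_signed == pytest.approx(brute_force_delta(a, b))
    assert d.delta_signed == pytest.approx(-cliffs_delta(b, a).delta_signed)
    assert d.delta_magnitude == abs(d.delta_signed)
    # invariant under strictly monotone transforms of both groups
    f = lambda x: np.exp(0.1 * np.asarray(x, dtype=float))
    assert cliffs_delta(f(a), f(b)).delta_signed == pytest.approx(d.delta_signed)
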