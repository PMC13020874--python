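"""Normalization pipeline: filter, TMM, RPKM, stable genes, rescaling."""

from __future__ import annotations

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from paralog_fates.normexpr import (
    compute_rpkm_log2,
    cross_species_factor,
    multimap_concordance_filter,
    normalize_pipeline,
    select_stable_genes,
    tmm_factors,
)
from paralog_fates.synth import (
    FateName,
    FateScenario,
    simulate_counts_from_expression,
    simulate_expression_pair_set,
)


def frame(data, samples=("s1", "s2")):
    genes = [f"g{i}" for i in range(len(data))]
    return pd.DataFrame(data, index=genes, columns=list(samples), dtype=float)


# -- multimap filter ---------------------------------------------------


def test_multimap_filter_rules():
    unique = frame([[100, 100], [100, 100], [0, 0]])
    fractional = frame([[110, 108], [100, 130], [5, 0]])
    kept, removed = multimap_concordance_filter(unique, fractional, threshold=0.2)
    assert kept == ["g0"]  # 10% discrepancy tolerated
    assert set(removed) == {"g1", "g2"}  # 30% in one sample; 5/max(0,1) at zero unique


def test_multimap_filter_summed_variant_and_index_check():
    unique = frame([[100, 100]])
    fractional = frame([[130, 90]])
    kept, _ = multimap_concordance_filter(unique, fractional, per_sample=False)
    assert kept == ["g0"]  # summed counts differ by 10% only
    with pytest.raises(ValueError):
        multimap_concordance_filter(unique, fractional.iloc[:, ::-1])


# -- TMM ---------------------------------------------------------------


def _toy_counts(seed=7, n_genes=20):
    rng = np.random.default_rng(seed)
    counts = pd.DataFrame(
        rng.poisson(rng.gamma(2.0, 200.0, size=(n_genes, 1)), size=(n_genes, 3)).astype(float),
        index=[f"g{i}" for i in range(n_genes)],
        columns=["ref", "s1", "s2"],
    )
    counts.loc["g0", "s1"] *= 8
    counts.loc["g1", "s1"] *= 6
    return counts


def test_tmm_fixed_points():
    counts = _toy_counts()
    f = tmm_factors(counts, "ref")
    assert f["ref"] == 1.0
    same = counts.copy()
    same["s1"] = counts["ref"]
    assert tmm_factors(same, "ref")["s1"] == pytest.approx(1.0)
    scaled = counts.copy()
    scaled["s1"] = counts["ref"] * 3  # proportions unchanged -> factor 1
    assert tmm_factors(scaled, "ref")["s1"] == pytest.approx(1.0)


def test_tmm_matches_stepwise_hand_computation():
    """Factor equals a direct independent evaluation of the trimmed weighted mean."""
    counts = _toy_counts()
    obs, ref = counts["s1"].to_numpy(), counts["ref"].to_numpy()
    lib_o, lib_r = obs.sum(), ref.sum()
    ok = (obs > 0) & (ref > 0)
    o, r = obs[ok], ref[ok]
    m = np.log2((o / lib_o) / (r / lib_r))
    a = 0.5 * np.log2((o / lib_o) * (r / lib_r))
    w = (lib_o - o) / (lib_o * o) + (lib_r - r) / (lib_r * r)
    n = len(m)
    keep = np.ones(n, bool)
    order_m = np.argsort(m, kind="stable")
    order_a = np.argsort(a, kind="stable")
    lo_m, hi_m = int(np.floor(n * 0.30)), int(np.ceil(n * 0.70))
    lo_a, hi_a = int(np.floor(n * 0.05)), int(np.ceil(n * 0.95))
    trimmed = np.zeros(n, bool)
    trimmed[order_m[:lo_m]] = True
    trimmed[order_m[hi_m:]] = True
    trimmed[order_a[:lo_a]] = True
    trimmed[order_a[hi_a:]] = True
    keep &= ~trimmed
    expected = 2 ** (np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep]))
    assert tmm_factors(counts, "ref")["s1"] == pytest.approx(expected)


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not on PATH")
def test_tmm_matches_edger(tmp_path):
    """Independent oracle: edgeR's calcNormFactors on the same fixture."""
    counts = _toy_counts(seed=11, n_genes=40)
    path = tmp_path / "counts.tsv"
    counts.to_csv(path, sep="\t")
    script = textwrap.dedent(
        f"""
        suppressMessages(library(edgeR))
        x <- as.matrix(read.delim("{path}", row.names=1))
        f <- calcNormFactors(x, method="TMM", refColumn=1)
        cat(f / f[1], sep="\\n")
        """
    )
    r = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True)
    assert r.returncode == 0, r.stderr
    edger = np.array([float(v) for v in r.stdout.split()])
    ours = tmm_factors(counts, "ref").to_numpy()
    np.testing.assert_allclose(ours, edger, rtol=1e-5)


# -- RPKM --------------------------------------------------------------


def test_rpkm_definition_and_scale_invariance(rng):
    counts = frame([[10, 0]])
    lengths = pd.Series({"g0": 1000})
    libs = pd.Series({"s1": 1e6, "s2": 1e6})
    out = compute_rpkm_log2(counts, lengths, libs)
    assert out.loc["g0", "s1"] == pytest.approx(np.log2(11))
    assert out.loc["g0", "s2"] == 0.0

    big = pd.DataFrame(
        rng.poisson(50, size=(30, 4)).astype(float),
        index=[f"g{i}" for i in range(30)], columns=list("abcd"),
    )
    lengths = pd.Series(rng.integers(300, 3000, 30), index=big.index)
    libs = pd.Series(rng.uniform(1e6, 1e7, 4), index=big.columns)
    doubled = compute_rpkm_log2(big * 2, lengths, libs * 2)
    pd.testing.assert_frame_equal(compute_rpkm_log2(big, lengths, libs), doubled)

    with pytest.raises(ValueError):
        compute_rpkm_log2(big, lengths, libs * 0)


# -- stable genes ------------------------------------------------------


def test_stable_gene_selection_rules(rng):
    n_genes, n_samples = 40, 6
    base = rng.normal(5, 2, size=(n_genes, 1)) + rng.normal(0, 0.3, size=(n_genes, n_samples))
    expr = pd.DataFrame(base, index=[f"g{i}" for i in range(n_genes)],
                        columns=[f"s{j}" for j in range(n_samples)])
    # g0: pinned to the exact median rank in every sample (zero rank SD)
    expr.loc["g0"] = expr.drop("g0").median(axis=0)
    # g1: globally highest everywhere -> excluded by the top-25% rule
    expr.loc["g1"] = expr.drop("g1").max(axis=0) + 10
    stable = select_stable_genes(expr, n_select=5)
    assert stable[0] == "g0"
    assert "g1" not in set(select_stable_genes(expr, n_select=len(expr)))


def test_stable_gene_selection_matches_bruteforce(rng):
    expr = pd.DataFrame(
        rng.normal(5, 2, size=(60, 5)),
        index=[f"g{i}" for i in range(60)], columns=[f"s{j}" for j in range(5)],
    )
    got = select_stable_genes(expr, n_select=10)
    # independent recomputation of the rank pipeline
    pct = expr.rank(axis=0, pct=True)
    med = pct.median(axis=1).sort_values(kind="mergesort")
    cut = int(np.floor(0.25 * len(med)))
    eligible = med.index[cut: len(med) - cut]
    sd = pct.loc[eligible].std(axis=1).sort_values(kind="mergesort")
    assert got == list(sd.index[:10])


def test_stable_gene_selection_warns_when_too_few(caplog):
    expr = pd.DataFrame(np.random.default_rng(0).normal(size=(8, 3)),
                        index=[f"g{i}" for i in range(8)], columns=list("abc"))
    got = select_stable_genes(expr, n_select=100)
    assert len(got) == 4  # 8 genes minus 25% trimmed at each end


# -- cross-species factor ---------------------------------------------


def test_cross_species_factor_fixed_points():
    expr = frame([[4, 2], [6, 3], [8, 4]], samples=("ref", "s"))
    stable = ["g0", "g1", "g2"]
    factors, norm = cross_species_factor(expr, stable, "ref")
    assert factors["ref"] == 1.0
    assert factors["s"] == pytest.approx(2.0)  # half the reference median
    meds = norm.loc[stable].median(axis=0)
    assert meds["ref"] == pytest.approx(meds["s"])
    with pytest.raises(ValueError):
        cross_species_factor(frame([[4, 0], [6, 0], [8, 0]], ("ref", "s")), stable, "ref")


# -- pipeline ----------------------------------------------------------


def _synthetic_counts(seed=5, n_pairs=20, n_single=120, noise=0.25):
    sc = FateScenario(FateName.REDUNDANT, noise_sd=noise)
    ds, _ = simulate_expression_pair_set(
        n_pairs, sc, n_tissues=6, pre_species=["pre1"],
        post_species=["post1", "post2", "post3"],
        seed=seed, n_single_copy_families=n_single,
    )
    counts, frac = simulate_counts_from_expression(
        ds, seed=seed + 1, composition_fraction=0.05
    )
    return ds, counts, frac


def test_pipeline_requires_raw_counts_stage():
    ds, counts, frac = _synthetic_counts()
    with pytest.raises(ValueError, match="stage"):
        normalize_pipeline(ds)  # RPKM-stage input refused


def test_pipeline_recovers_generating_profiles():
    """Depth and composition distortions are removed: per-sample rank
    correlation with the generating profiles stays high."""
    ds, counts, frac = _synthetic_counts()
    norm, report = normalize_pipeline(counts, counts_fractional=frac, n_stable=60)
    assert norm.stage == "normalized"
    truth = np.log2(ds.values + 1.0)
    for s in norm.samples:
        t, n = truth[s].dropna(), norm.values[s].dropna()
        common = t.index.intersection(n.index)
        assert spearmanr(t[common], n[common]).statistic >= 0.95
    # stable-gene medians equal across samples after rescaling
    og = norm.ortholog_matrix()
    meds = og.loc[report.stable_genes].median(axis=0)
    np.testing.assert_allclose(meds, meds.iloc[0], rtol=1e-9)


def test_pipeline_corrected_hook_substitutes_matrix():
    ds, counts, frac = _synthetic_counts(n_pairs=5, n_single=40)
    norm1, _ = normalize_pipeline(counts, n_stable=20)
    bad = pd.DataFrame(1.0, index=counts.values.index, columns=counts.values.columns)
    norm2, report = normalize_pipeline(counts, n_stable=20, corrected=bad)
    assert "substituted" in " ".join(report.warnings)
    assert not norm1.values.equals(norm2.values)
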