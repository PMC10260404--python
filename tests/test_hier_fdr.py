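import numpy as np
import pandas as pd
import pytest

from cellgp.hier_fdr import (CisWindow, HierarchicalEqtlModel, HierPriors,
                             build_cis_windows, enrichment_2x2,
                             stratified_enrichment)
from cellgp.synthetic_data import simulate_bf_windows


def _toy_windows():
    genes = pd.DataFrame({
        "gene": ["gA", "gB"],
        "chrom": ["1", "1"],
        "tss": [1_000_000, 5_000_000]})
    variants = pd.DataFrame({
        "variant": ["v1", "v2", "v3", "v4", "v5"],
        "chrom": ["1"] * 5,
        "pos": [600_000, 1_500_000, 1_500_001, 4_900_000, 5_000_000],
        "maf": [0.3, 0.05, 0.2, 0.4, 0.1]})
    return genes, variants


def test_build_cis_windows_membership_and_boundaries():
    genes, variants = _toy_windows()
    w = build_cis_windows(genes, variants)
    # hand enumeration: gA gets v1 (|d|=400k) and v3 (500,001 -> excluded);
    # v2 fails the strict MAF filter despite being in range
    assert list(w[0].variant_ids) == ["v1"]
    assert list(w[1].variant_ids) == ["v4", "v5"]
    # exact boundary: a variant at TSS + 500,000 is kept
    variants2 = variants.copy()
    variants2.loc[2, "pos"] = 1_500_000
    variants2.loc[1, "maf"] = 0.0500001
    w2 = build_cis_windows(genes, variants2)
    assert set(w2[0].variant_ids) == {"v1", "v2", "v3"}


def test_empty_window_flagged():
    genes = pd.DataFrame({"gene": ["gX"], "chrom": ["2"],
                          "tss": [1_000_000]})
    _, variants = _toy_windows()
    with pytest.warns(RuntimeWarning, match="no eligible variants"):
        w = build_cis_windows(genes, variants)
    assert w[0].n_variants == 0


def _window(gene, lbf, pos=None):
    l = len(lbf)
    pos = np.linspace(-400_000, 400_000, l).astype(int) if pos is None \
        else np.asarray(pos)
    return CisWindow(gene=gene, tss=0,
                     variant_ids=np.array([f"{gene}_v{i}"
                                           for i in range(l)]),
                     positions=pos, mafs=np.full(l, 0.3),
                     log_bf=np.asarray(lbf, dtype=float))


def test_uninformative_bfs_give_prior_posteriors():
    """All BFs equal to one: gene posterior equals the gene prior and
    variant posteriors stay uniform (no decay, no annotations)."""
    windows = [_window(f"g{i}", np.zeros(8)) for i in range(30)]
    res = HierarchicalEqtlModel(windows).fit(
        priors=HierPriors(pi_gene=0.1, distance_decay=0.0))
    assert np.allclose(res.z_gene, res.priors.pi_gene, atol=1e-10)
    assert res.priors.pi_gene == pytest.approx(0.1, abs=1e-6)
    for zv in res.z_variant:
        assert np.allclose(zv, 1.0 / 8, atol=1e-10)


def test_dominant_variant_takes_posterior_mass():
    lbf = np.zeros(10)
    lbf[3] = np.log(1e6)
    windows = [_window("g0", lbf)] + \
        [_window(f"g{i}", np.zeros(10)) for i in range(1, 20)]
    res = HierarchicalEqtlModel(windows).fit()
    assert res.z_variant[0][3] > 0.99
    assert res.lead_variant("g0") == "g0_v3"


def test_gene_posterior_monotone_in_regional_bf():
    windows = [_window(f"g{i}", np.full(5, b))
               for i, b in enumerate([0.0, 1.0, 2.0, 4.0])]
    res = HierarchicalEqtlModel(windows).fit(max_iter=3)
    assert np.all(np.diff(res.z_gene) > 0)


def test_variant_posteriors_sum_to_one_and_em_monotone():
    w, _ = simulate_bf_windows(n_genes=150, variants_per_gene=25,
                               pi=0.4, seed=3)
    res = HierarchicalEqtlModel(w).fit()
    for zv in res.z_variant:
        assert abs(zv.sum() - 1.0) < 1e-8
    tr = res.loglik_trace
    assert np.all(np.diff(tr) >= -1e-7 * np.abs(tr[:-1]))
    assert "Hierarchical" in res.summary()


def test_call_eqtls_strict_boundary():
    windows = [_window("hi", np.full(4, 8.0)),
               _window("lo", np.zeros(4))]
    res = HierarchicalEqtlModel(windows).fit(max_iter=3)
    res.z_gene = np.array([0.95, 0.90])
    assert res.call_eqtls(lfdr=0.10) == ["hi"]  # 0.90 exactly: not called


def test_lead_variant_tie_breaks():
    w = _window("g0", [1.0, 1.0, 0.0], pos=[-200_000, 100_000, 300_000])
    res = HierarchicalEqtlModel([w]).fit(
        max_iter=2, priors=HierPriors(0.1, 0.0))
    # equal BFs and flat prior tie the top two; nearer TSS wins
    assert res.lead_variant("g0") == "g0_v1"


def test_enrichment_hand_table():
    # binary toy table (T00,T01,T10,T11) = (20,30,10,40)
    x = np.array([0] * 50 + [1] * 50)
    z = np.array([0] * 20 + [1] * 30 + [0] * 10 + [1] * 40)
    res = enrichment_2x2(x, z)
    assert res.log_odds == pytest.approx(np.log(8 / 3), abs=1e-12)
    assert not res.corrected
    assert res.se == pytest.approx(
        np.sqrt(1 / 20 + 1 / 30 + 1 / 10 + 1 / 40), abs=1e-12)


def test_enrichment_matches_statsmodels_woolf():
    """Binary inputs reduce to the classical 2x2 log odds ratio."""
    import statsmodels.api as sm
    rng = np.random.default_rng(1)
    x = rng.integers(0, 2, 400)
    z = ((0.3 * x + rng.random(400)) > 0.6).astype(float)
    res = enrichment_2x2(x, z)
    t22 = sm.stats.Table2x2(res.table, shift_zeros=False)
    assert res.log_odds == pytest.approx(t22.log_oddsratio, abs=1e-10)
    assert res.se == pytest.approx(t22.log_oddsratio_se, abs=1e-10)


def test_enrichment_perfect_association_corrected():
    x = np.array([0] * 50 + [1] * 50)
    res = enrichment_2x2(x, x)
    assert res.corrected and res.log_odds > 0


def test_enrichment_null_is_small():
    rng = np.random.default_rng(0)
    x = rng.integers(0, 2, 10_000)
    z = rng.integers(0, 2, 10_000)
    assert abs(enrichment_2x2(x, z).log_odds) < 0.1


def test_stratified_reduces_to_plain_with_one_bin():
    rng = np.random.default_rng(2)
    x = rng.integers(0, 2, 300).astype(float)
    z = rng.random(300)
    c = rng.random(300)
    plain = enrichment_2x2(x, z)
    strat = stratified_enrichment(x, z, c, n_bins=1)
    assert strat.log_odds == pytest.approx(plain.log_odds, abs=1e-12)
    assert strat.se == pytest.approx(plain.se, abs=1e-12)


def test_stratified_identical_bins_halve_variance():
    x = np.array([0] * 50 + [1] * 50)
    z = np.array([0] * 20 + [1] * 30 + [0] * 10 + [1] * 40)
    x1 = np.concatenate([x, x])
    z1 = np.concatenate([z, z])
    c = np.concatenate([np.zeros(100), np.ones(100)])
    single = enrichment_2x2(x, z)
    meta = stratified_enrichment(x1, z1, c, n_bins=2)
    assert meta.log_odds == pytest.approx(single.log_odds, abs=1e-10)
    assert meta.se**2 == pytest.approx(single.se**2 / 2, abs=1e-10)


def test_stratified_removes_confounding():
    """X and Z both driven by a confounder C but independent given C:
    the stratified estimate is near zero while the plain one is inflated."""
    rng = np.random.default_rng(3)
    n = 20_000
    c = rng.standard_normal(n)
    x = (c + rng.standard_normal(n) > 0).astype(float)
    z = (c + rng.standard_normal(n) > 0).astype(float)
    assert abs(enrichment_2x2(x, z).log_odds) > 0.5
    adj = stratified_enrichment(x, z, c, n_bins=100)
    assert abs(adj.log_odds) < 0.15


def test_hierarchical_model_with_annotations_recovers_enrichment():
    """Variants carrying a planted annotation are preferentially causal;
    the EM recovers a positive annotation log-odds."""
    rng = np.random.default_rng(4)
    from cellgp.coloc import wakefield_abf
    windows = []
    for gi in range(400):
        l = 20
        ann = (rng.random(l) < 0.2).astype(float)[:, None]
        w_prior = np.exp(1.5 * ann[:, 0])
        effect = np.zeros(l)
        if rng.random() < 0.5:
            ci = rng.choice(l, p=w_prior / w_prior.sum())
            effect[ci] = rng.normal(0, 0.2)
        bh = rng.normal(effect, 0.05)
        windows.append(CisWindow(
            gene=f"g{gi}", tss=0,
            variant_ids=np.array([f"g{gi}_v{i}" for i in range(l)]),
            positions=rng.integers(-400_000, 400_000, l),
            mafs=np.full(l, 0.3),
            log_bf=wakefield_abf(bh, np.full(l, 0.05), 0.04),
            annotations=ann))
    res = HierarchicalEqtlModel(windows, n_annotations=1).fit()
    assert 0.5 < res.priors.annotation_logodds[0] < 3.0
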