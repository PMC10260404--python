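import hashlib
import subprocess
import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from cellgp.io import (read_expression, read_vcf_dosages, save_context,
                       load_context, write_expression, write_vcf)
from cellgp.qc import (QcThresholds, genotype_from_ase, grid_aggregate,
                       logcpm, qc_filter_cells)


def _counts_frame(fragments, n_genes=700, mito=0.0, top100_share=0.1):
    """One-cell count matrix hitting the requested QC metrics."""
    counts = np.zeros(n_genes)
    n_expr = 600
    top = top100_share * fragments
    counts[:100] = top / 100
    counts[100:n_expr] = (fragments - top) / (n_expr - 100)
    mito_counts = mito / (100 - mito) * fragments if mito else 0.0
    counts = np.append(counts, mito_counts)
    genes = [f"g{i}" for i in range(n_genes)] + ["mt1"]
    ann = pd.DataFrame({"chrom": ["1"] * n_genes + ["MT"]}, index=genes)
    return pd.DataFrame(counts[None, :], index=["cell0"], columns=genes), ann


@pytest.mark.parametrize("fragments,mito,top,expect", [
    (9_500, 10.0, 10.0, False),     # too few fragments
    (15_000, 10.0, 25.0, True),     # passes all four cuts
    (10_000, 10.0, 10.0, False),    # exactly 10,000: strict boundary
    (15_000, 25.0, 10.0, False),    # mitochondrial fraction too high
    (15_000, 10.0, 35.0, False),    # low complexity
])
def test_qc_filter_thresholds(fragments, mito, top, expect):
    counts, ann = _counts_frame(fragments, mito=mito, top100_share=top / 100)
    rep = qc_filter_cells(counts, ann)
    assert bool(rep["pass"].iloc[0]) is expect


def test_qc_gene_count_threshold():
    counts, ann = _counts_frame(15_000)
    few = counts.copy()
    few.iloc[0, 300:601] = 0.0  # only 300 genes detected
    few.iloc[0, :100] *= 3      # keep fragments high
    rep = qc_filter_cells(few, ann)
    assert rep["genes_detected"].iloc[0] <= 500
    assert not rep["pass"].iloc[0]


def test_qc_requires_annotation():
    counts, ann = _counts_frame(15_000)
    with pytest.raises(ValueError, match="annotation"):
        qc_filter_cells(counts, ann.iloc[:10])


def test_logcpm_closed_forms():
    counts = np.array([[0, 5, 5]])
    out = logcpm(counts)
    assert out[0, 0] == 0.0
    assert out[0, 1] == pytest.approx(np.log1p(1e6 * 0.5))
    # count == library size
    assert logcpm(np.array([[7, 0]]))[0, 0] == pytest.approx(
        np.log1p(1e6))
    # monotone within a cell
    c = np.array([[1, 2, 5, 100]])
    assert np.all(np.diff(logcpm(c)[0]) > 0)
    with pytest.raises(ValueError, match="library"):
        logcpm(np.zeros((1, 3)))


def test_grid_aggregate_constant_and_geomean():
    coords = np.array([[0.0, 0.0], [0.1, 0.1], [5.0, 5.0]])
    out = grid_aggregate(np.array([2.0, 2.0, 2.0]), coords, n_grid=3)
    assert np.allclose(out["value_0"], 2.0)
    out2 = grid_aggregate(np.array([1.0, 4.0, 9.0]), coords, n_grid=3)
    cell = out2[out2["n_cells"] == 2]["value_0"].iloc[0]
    assert cell == pytest.approx(2.0)  # sqrt(1 * 4)


def test_grid_aggregate_membership_hand_placed():
    # 3x3 grid over [0,3]x[0,3]: cell (i,j) from floor of coordinates
    pts = np.array([[0.1, 0.1], [0.2, 0.4], [1.5, 0.5], [2.9, 2.9],
                    [2.2, 0.1], [0.5, 2.5], [1.1, 1.1], [1.9, 1.9],
                    [0.0, 0.0], [3.0, 3.0]])
    out = grid_aggregate(np.ones(10), pts, n_grid=3)
    got = {(r.grid_x, r.grid_y): r.n_cells for r in out.itertuples()}
    assert got == {(0, 0): 3, (1, 0): 1, (2, 2): 2, (2, 0): 1,
                   (0, 2): 1, (1, 1): 2}


def test_grid_aggregate_zero_exclusion_counted():
    coords = np.zeros((3, 2))
    out = grid_aggregate(np.array([0.0, 4.0, 9.0]), coords, n_grid=3)
    assert out["n_excluded"].iloc[0] == 1
    assert out["value_0"].iloc[0] == pytest.approx(6.0)  # sqrt(36)


@pytest.mark.parametrize("ref,alt,expect", [
    (10, 0, 0), (5, 5, 1), (0, 12, 2), (0, 0, None),
])
def test_genotype_from_ase_calls(ref, alt, expect):
    geno, ll = genotype_from_ase(ref, alt)
    assert geno == expect
    assert ll.shape == (3,)


def test_genotype_from_ase_exact_binomial_logliks():
    # hand-computed: Binom(alt=0; n=10, p=0.01) and p=0.5
    _, ll = genotype_from_ase(10, 0)
    assert ll[0] == pytest.approx(10 * np.log(0.99), abs=1e-10)
    assert ll[1] == pytest.approx(10 * np.log(0.5), abs=1e-10)
    # ambiguous margin is reported as undetermined
    geno, _ = genotype_from_ase(4, 1)
    assert geno is None
    with pytest.raises(ValueError):
        genotype_from_ase(-1, 2)


def test_vcf_round_trip(tmp_path):
    rng = np.random.default_rng(0)
    variants = pd.DataFrame({
        "variant": [f"v{i}" for i in range(8)],
        "chrom": ["1"] * 8,
        "pos": np.arange(1, 9) * 1000,
    })
    geno = pd.DataFrame(rng.integers(0, 3, size=(10, 8)),
                        index=[f"d{i}" for i in range(10)],
                        columns=variants["variant"])
    path = tmp_path / "test.vcf"
    write_vcf(path, variants, geno)
    dosages, var_meta = read_vcf_dosages(path)
    assert np.array_equal(dosages.to_numpy(),
                          geno[var_meta["variant"]].to_numpy())
    assert list(dosages.index) == list(geno.index)
    # MAF: allele counting over donors
    af = geno[var_meta["variant"]].to_numpy().mean(axis=0) / 2
    assert np.allclose(var_meta["maf"], np.minimum(af, 1 - af))


def test_vcf_maf_example(tmp_path):
    # 10 donors, 3 alt alleles at one site -> MAF 0.15
    variants = pd.DataFrame({"variant": ["v0"], "chrom": ["1"],
                             "pos": [100]})
    geno = pd.DataFrame({"v0": [2, 1, 0, 0, 0, 0, 0, 0, 0, 0]},
                        index=[f"d{i}" for i in range(10)])
    path = tmp_path / "m.vcf"
    write_vcf(path, variants, geno)
    _, meta = read_vcf_dosages(path)
    assert meta["maf"].iloc[0] == pytest.approx(0.15)


def test_expression_round_trip(tmp_path):
    rng = np.random.default_rng(1)
    y = rng.normal(size=(6, 4))
    cells = pd.DataFrame({"cell": [f"c{i}" for i in range(6)]})
    genes = pd.DataFrame({"gene": [f"g{i}" for i in range(4)]})
    write_expression(tmp_path, y, cells, genes)
    y2, c2, g2 = read_expression(tmp_path)
    assert np.allclose(y, y2, atol=1e-12)
    assert list(c2["cell"]) == list(cells["cell"])


def test_context_round_trip(tmp_path, two_branch_data):
    from cellgp.synthetic_data import truth_context
    _, _, _, truth = two_branch_data
    ctx = truth_context(truth)
    save_context(tmp_path / "ctx.npz", ctx)
    ctx2 = load_context(tmp_path / "ctx.npz")
    assert np.array_equal(ctx.X, ctx2.X)
    assert ctx2.v_gp == ctx.v_gp and ctx2.kernel_mode == ctx.kernel_mode
    assert np.allclose(ctx.K_baseline(), ctx2.K_baseline())


def _run_cli(args, cwd):
    return subprocess.run([sys.executable, "-m", "cellgp.cli", *args],
                          cwd=cwd, capture_output=True, text=True)


def test_cli_pipeline_end_to_end(tmp_path):
    """simulate -> qc -> fit-latent -> classify-genes -> map-eqtl -> fdr ->
    coloc on a miniature dataset exits zero at every stage."""
    sim = ["simulate", "--out", "sim", "--seed", "1", "--donors", "4",
           "--cells-per-donor", "25", "--genes", "60",
           "--variants-per-gene", "4"]
    stages = [
        sim,
        ["qc", "--data", "sim", "--out", "qc", "--min-fragments", "10",
         "--min-genes", "5", "--max-top100-pct", "101"],
        ["fit-latent", "--data", "sim", "--out", "fit", "--seed", "1",
         "--inducing", "20", "--max-iter", "60"],
        ["classify-genes", "--data", "sim", "--fit", "fit", "--out", "de",
         "--restarts", "1"],
        ["map-eqtl", "--data", "sim", "--fit", "fit", "--out", "eq",
         "--max-genes", "25"],
        ["fdr", "--data", "sim", "--bf", "eq", "--out", "fdr"],
        ["coloc", "--bf", "eq", "--gwas", "sim/gwas.tsv", "--out", "co"],
    ]
    for args in stages:
        res = _run_cli(args, tmp_path)
        assert res.returncode == 0, f"{args[0]} failed: {res.stderr[-800:]}"
    for f in ("qc/qc_report.tsv", "fit/context.npz", "de/gene_classes.tsv",
              "de/pseudotime.tsv", "eq/eqtl_bf.tsv", "fdr/eqtl_calls.tsv",
              "co/coloc.tsv"):
        assert (tmp_path / f).exists()
    co = pd.read_csv(tmp_path / "co/coloc.tsv", sep="\t")
    post = co[["p_h0", "p_h1", "p_h2", "p_h3", "p_h4"]].to_numpy()
    assert np.allclose(post.sum(axis=1), 1.0, atol=1e-6)

    # deterministic stages reproduce bit-identical artifacts under a seed
    res = _run_cli(sim[:2] + ["sim2"] + sim[3:], tmp_path)
    assert res.returncode == 0
    h1 = hashlib.sha256((tmp_path / "sim/matrix.mtx").read_bytes())
    h2 = hashlib.sha256((tmp_path / "sim2/matrix.mtx").read_bytes())
    assert h1.hexdigest() == h2.hexdigest()

    # invalid options are rejected with a nonzero exit
    bad = _run_cli(["simulate", "--out", "x", "--donorz", "3"], tmp_path)
    assert bad.returncode != 0 and "donorz" in bad.stderr
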