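"""Synthetic-data generator: determinism, marginal structure, LD recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mirwin import (PanelSpec, SignalSpec, gen_alda_scores, gen_eqtl_list,
                    gen_mirna_annotations, gen_reference_panel,
                    gen_summary_stats)
from mirwin.annotations import load_mirna_annotations


def test_panel_shape_and_dosage_range():
    spec = PanelSpec(n_haplotypes=100, n_snps_per_block=3, n_blocks=2, seed=0)
    panel = gen_reference_panel(spec)
    assert panel.snp_map.shape[0] == 6
    assert panel.genotypes.shape == (50, 6)
    assert set(np.unique(panel.genotypes)) <= {0, 1, 2}


def test_panel_positions_strictly_increasing_within_chromosome():
    spec = PanelSpec(n_haplotypes=100, n_snps_per_block=5, n_blocks=24, seed=1)
    panel = gen_reference_panel(spec)
    for _, grp in panel.snp_map.groupby("CHR"):
        assert grp["BP"].is_monotonic_increasing
        assert grp["BP"].is_unique


def test_panel_maf_within_requested_range():
    spec = PanelSpec(n_haplotypes=500, n_snps_per_block=20, n_blocks=5,
                     maf_range=(0.1, 0.4), seed=2)
    panel = gen_reference_panel(spec)
    freq = panel.genotypes.mean(axis=0) / 2
    maf = np.minimum(freq, 1 - freq)
    assert np.all(maf >= 0.1 - 1e-12) and np.all(maf <= 0.4 + 1e-12)


def test_overlapping_block_layout_rejected():
    layout = {0: ("1", 1000, 100), 1: ("1", 1500, 100)}
    spec = PanelSpec(n_haplotypes=100, n_snps_per_block=10, n_blocks=2,
                     chromosome_layout=layout, seed=0)
    with pytest.raises(ValueError, match="overlap"):
        gen_reference_panel(spec)


def test_vcf_output_deterministic(tmp_path):
    spec = PanelSpec(n_haplotypes=60, n_snps_per_block=4, n_blocks=2, seed=5)
    paths = []
    for name in ("a.vcf", "b.vcf"):
        panel = gen_reference_panel(spec)
        p = tmp_path / name
        panel.to_vcf(str(p))
        paths.append(p)
    assert paths[0].read_bytes() == paths[1].read_bytes()


def test_zero_rho_blocks_nearly_uncorrelated():
    """With block_rho=0 the mean |off-diagonal| genotype correlation is small."""
    devs = []
    for seed in range(20):
        spec = PanelSpec(n_haplotypes=2_000, n_snps_per_block=8, n_blocks=1,
                         block_rho=0.0, seed=seed)
        panel = gen_reference_panel(spec)
        R = np.corrcoef(panel.genotypes.astype(float), rowvar=False)
        off = R[~np.eye(R.shape[0], dtype=bool)]
        devs.append(np.abs(off).mean())
    assert max(devs) < 0.1


def test_ld_decays_as_rho_power_distance(big_panel):
    """Estimated genotype correlation reproduces rho^|i-j| (MAE < 0.05)."""
    rho = big_panel.spec.block_rho
    errs = []
    for b in range(big_panel.spec.n_blocks):
        G = big_panel.genotypes[:, big_panel.block_columns(b)].astype(float)
        R = np.corrcoef(G, rowvar=False)
        m = R.shape[0]
        idx = np.arange(m)
        target = rho ** np.abs(idx[:, None] - idx[None, :])
        errs.append(np.abs(R - target).mean())
    assert np.mean(errs) < 0.05


def test_null_pvalues_uniform():
    """Null p-values pass a KS test against Uniform(0,1) at n=10,000."""
    spec = PanelSpec(n_haplotypes=400, n_snps_per_block=50, n_blocks=200,
                     block_rho=0.0, seed=3)
    panel = gen_reference_panel(spec)
    ss = gen_summary_stats(panel, seed=4)
    d, _ = stats.kstest(ss["P"], "uniform")
    # 1% critical value of the KS distance at n=10,000
    assert d < 1.63 / np.sqrt(len(ss))
    assert ((ss["P"] > 0) & (ss["P"] <= 1)).all()


def test_noncentrality_shifts_mean_abs_z(small_panel):
    causal = small_panel.snp_map["SNP"].iloc[5]
    sig = SignalSpec(causal_snp_ids=frozenset([causal]), noncentrality=5.0)
    zs = [gen_summary_stats(small_panel, sig, seed=s).set_index("SNP").loc[causal, "Z"]
          for s in range(500)]
    mean_abs = np.mean(np.abs(zs))
    # |z| ~ folded normal(5, 1): mean ~ 5.0000 (folding negligible at nc=5)
    assert abs(mean_abs - 5.0) < 3 / np.sqrt(500)


def test_empty_causal_set_equals_null(small_panel):
    a = gen_summary_stats(small_panel, SignalSpec(), seed=9)
    b = gen_summary_stats(small_panel,
                          SignalSpec(causal_snp_ids=frozenset(),
                                     noncentrality=5.0), seed=9)
    pd.testing.assert_frame_equal(a, b)


def test_unknown_causal_snp_rejected(small_panel):
    with pytest.raises(ValueError, match="not in panel"):
        gen_summary_stats(small_panel,
                          SignalSpec(causal_snp_ids=frozenset(["rsNOPE"]),
                                     noncentrality=1.0), seed=0)


def test_mirna_annotations_counts_and_bounds(small_panel, tmp_path):
    out = tmp_path / "m.gff3"
    df = gen_mirna_annotations(5, small_panel.snp_map, seed=6,
                               non_autosomal_fraction=0.4, out_path=str(out))
    assert len(df) == 5
    assert (df["chrom"] == "X").sum() == 2
    lengths = df["tx_end"] - df["tx_start"] + 1
    assert lengths.between(60, 150).all()
    # written GFF3 round-trips through the loader
    recs = load_mirna_annotations(str(out))
    assert len(recs) == 5
    df2 = gen_mirna_annotations(5, small_panel.snp_map, seed=6,
                                non_autosomal_fraction=0.4,
                                out_path=str(tmp_path / "m2.gff3"))
    assert out.read_bytes() == (tmp_path / "m2.gff3").read_bytes()
    pd.testing.assert_frame_equal(df, df2)


def test_alda_scores_ranges_and_determinism(tmp_path):
    df = gen_alda_scores(100, seed=8, out_path=str(tmp_path / "a.csv"))
    assert len(df) == 100
    assert df["A"].between(0, 10).all()
    btot = df[[f"B{i}" for i in range(1, 6)]].sum(axis=1)
    assert btot.between(0, 10).all()
    for i in range(1, 6):
        assert df[f"B{i}"].isin([0, 1, 2]).all()
    df2 = gen_alda_scores(100, seed=8, out_path=str(tmp_path / "b.csv"))
    assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()
    pd.testing.assert_frame_equal(df, df2)


def test_eqtl_list_fraction_and_identity(small_panel):
    all_ids = gen_eqtl_list(small_panel.snp_map, fraction=1.0, seed=0)
    assert sorted(all_ids) == sorted(small_panel.snp_map["SNP"])
    sub = gen_eqtl_list(small_panel.snp_map, fraction=0.1, seed=0)
    assert len(sub) == round(0.1 * len(small_panel.snp_map))
    assert set(sub) <= set(small_panel.snp_map["SNP"])


def _enrichment_p_for_seed(seed, window_bias):
    """Enrichment p for one synthetic cohort whose signal sits in windows."""
    from mirwin.annotations import (MirnaRecord, expand_window,
                                    filter_autosomal)
    from mirwin.inference import eqtl_enrichment

    panel = gen_reference_panel(PanelSpec(n_haplotypes=400,
                                          n_snps_per_block=30, n_blocks=15,
                                          block_rho=0.5, seed=seed))
    ann = gen_mirna_annotations(4, panel.snp_map, seed=seed,
                                non_autosomal_fraction=0.0)
    records, _ = filter_autosomal(
        [MirnaRecord(r.name, str(r.chrom), int(r.tx_start), int(r.tx_end))
         for r in ann.itertuples(index=False)])
    windows = [expand_window(r) for r in records]
    chroms = panel.snp_map["CHR"].astype(str).to_numpy()
    pos = panel.snp_map["BP"].to_numpy()
    in_w = np.zeros(len(panel.snp_map), dtype=bool)
    for w in windows:
        in_w |= (chroms == w.chrom) & (pos >= w.win_start) & (pos <= w.win_end)
    rng = np.random.default_rng(seed + 1000)
    causal = frozenset(rng.choice(panel.snp_map["SNP"].to_numpy()[in_w], 15,
                                  replace=False))
    ss = gen_summary_stats(panel, SignalSpec(causal_snp_ids=causal,
                                             noncentrality=5.0),
                           seed=seed + 77)
    eqtl = gen_eqtl_list(panel.snp_map, fraction=0.2, seed=seed + 5,
                         windows=windows, window_bias=window_bias)
    _, p = eqtl_enrichment(ss, eqtl, alpha=0.05)
    return p


def test_window_biased_eqtl_list_detected_by_fisher():
    """With the eQTL list strongly biased into signal-bearing windows, the
    one-sided Fisher test rejects at 0.05 in >= 80% of 50 seeds."""
    hits = sum(_enrichment_p_for_seed(s, window_bias=100.0) < 0.05
               for s in range(50))
    assert hits >= 40, f"only {hits}/50 seeds detected the enrichment"
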