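"""Filtering, rank collapse, minor-taxon aggregation and Hellinger PCA."""

import numpy as np
import pandas as pd
import pytest

from hydrodeg import (
    OTHER_LABEL,
    AbundanceTable,
    aggregate_minor,
    collapse_to_rank,
    filter_asvs,
    hellinger,
    parse_lineage,
    pca,
    to_relative,
)
from conftest import random_counts_table


# ---------------------------------------------------------------- filter


def test_filter_removes_offdomain_unclassified_and_organelles(counts_table):
    filtered, audit = filter_asvs(counts_table, domain_keep="Bacteria")
    assert set(filtered.taxon_ids) == {"asv1", "asv2", "asv3"}
    assert audit.n_off_domain == 1      # Eukarya
    assert audit.n_organelle == 1       # Chloroplast lineage
    assert audit.n_unclassified_domain == 0
    assert not audit.empty_result


def test_filter_removes_domain_unclassified():
    t = AbundanceTable(
        pd.DataFrame({"a": [1.0], "b": [1.0]}, index=["s"]),
        lineage_of={"a": parse_lineage("Bacteria;P")},  # b has no lineage
    )
    filtered, audit = filter_asvs(t)
    assert filtered.taxon_ids == ["a"]
    assert audit.n_unclassified_domain == 1


def test_filter_mitochondria_at_any_rank():
    t = AbundanceTable(
        pd.DataFrame({"a": [1.0]}, index=["s"]),
        lineage_of={"a": parse_lineage("Bacteria;P;C;Rickettsiales;Mitochondria")},
    )
    filtered, audit = filter_asvs(t)
    assert audit.n_organelle == 1 and audit.empty_result


def test_filter_counts_are_untouched(counts_table):
    filtered, _ = filter_asvs(counts_table)
    for tax in filtered.taxon_ids:
        assert (filtered.data[tax] == counts_table.data[tax]).all()


def test_filter_relative_modes(counts_table):
    rel = to_relative(counts_table)
    closed, _ = filter_asvs(rel)
    assert closed.mode == "relative"
    assert np.allclose(closed.data.sum(axis=1), 1.0)
    raw, _ = filter_asvs(rel, renormalize=False)
    assert raw.mode == "counts"
    for tax in raw.taxon_ids:
        assert (raw.data[tax] == rel.data[tax]).all()


# ---------------------------------------------------------------- collapse


def test_collapse_merges_same_genus(counts_table):
    g = collapse_to_rank(counts_table, "genus")
    # asv1+asv2 share the Sphingomonas lineage
    assert g.data.loc["s2", "Sphingomonas"] == 20.0
    assert "unclassified_Bacillaceae" in g.taxon_ids  # asv3, family only


def test_collapse_conserves_per_sample_totals(counts_table):
    for rank in ("phylum", "family", "genus"):
        g = collapse_to_rank(counts_table, rank)
        assert (g.data.sum(axis=1) == counts_table.data.sum(axis=1)).all()


def test_collapse_unknown_rank():
    t = AbundanceTable(pd.DataFrame({"a": [1.0]}, index=["s"]))
    with pytest.raises(ValueError, match="unknown rank"):
        collapse_to_rank(t, "species")


def test_collapse_separates_homonym_genera_under_different_families():
    t = AbundanceTable(
        pd.DataFrame({"a": [1.0], "b": [2.0]}, index=["s"]),
        lineage_of={
            "a": parse_lineage("Bacteria;P;C;O;FamX;Twin"),
            "b": parse_lineage("Bacteria;P;C;O;FamY;Twin"),
        },
    )
    g = collapse_to_rank(t, "genus")
    assert g.n_taxa == 2  # distinct lineage prefixes stay distinct
    assert g.data.sum(axis=1).iloc[0] == 3.0


def test_collapse_random_tables_conserve(tmp_path):
    rng = np.random.default_rng(3)
    for _ in range(20):
        t = random_counts_table(rng)
        g = collapse_to_rank(t, "genus")
        assert (g.data.sum(axis=1) == t.data.sum(axis=1)).all()


# ---------------------------------------------------------------- aggregate


def rel(frame):
    return AbundanceTable(frame, mode="relative")


def test_aggregate_merges_below_threshold():
    frame = pd.DataFrame(
        {"big": [0.5, 0.6], "edge": [0.02, 0.01], "tiny": [0.019, 0.015]},
        index=["s1", "s2"],
    )
    frame["rest"] = 1.0 - frame.sum(axis=1)
    out = aggregate_minor(rel(frame), 2.0)
    assert "tiny" not in out.taxon_ids        # peaks at 1.9% < 2%
    assert "edge" in out.taxon_ids            # reaches exactly 2.0% -> retained
    assert OTHER_LABEL in out.taxon_ids
    assert np.allclose(out.data.sum(axis=1), frame.sum(axis=1), atol=1e-12)


def test_aggregate_is_idempotent():
    rng = np.random.default_rng(8)
    frame = pd.DataFrame(rng.dirichlet(np.ones(30) * 0.3, size=6),
                         index=[f"s{i}" for i in range(6)],
                         columns=[f"t{j}" for j in range(30)])
    once = aggregate_minor(rel(frame), 5.0)
    twice = aggregate_minor(once, 5.0)
    pd.testing.assert_frame_equal(once.data, twice.data)


def test_aggregate_threshold_validation():
    t = rel(pd.DataFrame({"a": [1.0]}, index=["s"]))
    for bad in (0.0, 100.0, -1.0):
        with pytest.raises(ValueError, match="threshold"):
            aggregate_minor(t, bad)


# ---------------------------------------------------------------- hellinger


def test_hellinger_forced_values():
    t = rel(pd.DataFrame({"a": [0.25], "b": [0.25], "c": [0.5]}, index=["s"]))
    h = hellinger(t)
    assert list(h.loc["s"]) == pytest.approx([0.5, 0.5, 0.70710678], abs=1e-8)


def test_hellinger_rows_have_unit_norm():
    rng = np.random.default_rng(1)
    frame = pd.DataFrame(rng.dirichlet(np.ones(12), size=5),
                         index=[f"s{i}" for i in range(5)],
                         columns=[f"t{j}" for j in range(12)])
    h = hellinger(rel(frame))
    assert np.allclose(np.linalg.norm(h.values, axis=1), 1.0, atol=1e-12)
    # zeros stay zero
    frame.iloc[0, 0] = 0.0
    frame.iloc[0] /= frame.iloc[0].sum()
    assert hellinger(rel(frame)).iloc[0, 0] == 0.0


def test_hellinger_converts_counts_internally(counts_table):
    h = hellinger(counts_table)
    assert np.allclose(np.linalg.norm(h.values, axis=1), 1.0, atol=1e-12)


# ---------------------------------------------------------------- pca


def test_pca_matches_eigendecomposition_oracle():
    rng = np.random.default_rng(4)
    m = pd.DataFrame(rng.random((4, 3)), index=list("wxyz"), columns=list("abc"))
    res = pca(m, n_axes=3)

    x = m.values - m.values.mean(axis=0)
    cov = x.T @ x
    evals, evecs = np.linalg.eigh(cov)
    evals, evecs = evals[::-1], evecs[:, ::-1]
    frac_oracle = evals / evals.sum()
    scores_oracle = x @ evecs

    assert res.axis_variance_fraction == pytest.approx(frac_oracle[:3], abs=1e-10)
    for i in range(3):
        got = res.sample_scores.values[:, i]
        want = scores_oracle[:, i]
        # same axis up to sign
        assert (np.allclose(got, want, atol=1e-10)
                or np.allclose(got, -want, atol=1e-10))


def test_pca_variance_fractions_sum_to_one_full_rank():
    rng = np.random.default_rng(10)
    m = pd.DataFrame(rng.random((6, 5)))
    res = pca(m, n_axes=5)
    assert res.axis_variance_fraction.sum() == pytest.approx(1.0, abs=1e-9)
    assert (np.diff(res.axis_variance_fraction) <= 1e-12).all()  # non-increasing


def test_pca_sign_convention_is_deterministic():
    rng = np.random.default_rng(2)
    m = pd.DataFrame(rng.random((5, 4)))
    res = pca(m, n_axes=3)
    for ax in res.sample_scores.columns:
        load = res.taxon_loadings[ax].values
        assert load[np.argmax(np.abs(load))] > 0


def test_pca_degenerate_identical_samples():
    m = pd.DataFrame([[0.5, 0.5]] * 3, columns=["a", "b"])
    res = pca(m, n_axes=2)
    assert res.degenerate
    assert (res.axis_variance_fraction == 0).all()
    assert (res.sample_scores.values == 0).all()


def test_pca_input_validation():
    m = pd.DataFrame([[1.0, 2.0]])
    with pytest.raises(ValueError, match="at least 2 samples"):
        pca(m)
    m2 = pd.DataFrame([[1.0, 2.0], [3.0, 4.0]])
    with pytest.raises(ValueError, match="n_axes"):
        pca(m2, n_axes=5)


def test_hellinger_pca_equals_pcoa_on_hellinger_distances():
    """Classical MDS of Hellinger distances reproduces the PCA variance
    spectrum (Gower double-centering oracle)."""
    rng = np.random.default_rng(6)
    frame = pd.DataFrame(rng.dirichlet(np.ones(7), size=5),
                         index=[f"s{i}" for i in range(5)],
                         columns=[f"t{j}" for j in range(7)])
    h = hellinger(rel(frame))
    res = pca(h, n_axes=4)

    d2 = ((h.values[:, None, :] - h.values[None, :, :]) ** 2).sum(axis=2)
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    evals = np.sort(np.linalg.eigvalsh(b))[::-1]
    evals = np.clip(evals, 0, None)

    pca_eigs = res.axis_variance_fraction * (evals.sum())
    assert pca_eigs == pytest.approx(evals[:4], abs=1e-10)


# ---------------------------------------------------------------- pipeline


def test_filter_collapse_aggregate_conserve_counts():
    rng = np.random.default_rng(12)
    for _ in range(10):
        t = random_counts_table(rng, n_samples=3, n_taxa=10)
        filtered, _ = filter_asvs(t)
        assert (filtered.data.sum(axis=1)
                == t.data[filtered.taxon_ids].sum(axis=1)).all()
        g = collapse_to_rank(filtered, "genus")
        assert (g.data.sum(axis=1) == filtered.data.sum(axis=1)).all()
        relg = to_relative(g)
        agg = aggregate_minor(relg, 5.0)
        assert np.allclose(agg.data.sum(axis=1), relg.data.sum(axis=1), atol=1e-12)
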