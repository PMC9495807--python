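"""DCA gradient lengths and RDA against independent oracles."""

import numpy as np
import pandas as pd
import pytest

import copeind as ci
from copeind.errors import ValidationError
from copeind.ordination import DCA, RDA


def coenocline(G, n_sites=40, n_species=120, tol=1.0):
    """Noise-free Gaussian species responses along a gradient of G SD of
    species turnover; optima extend past the sampled range so edge sites
    see full response curves."""
    x = np.linspace(0, G, n_sites)
    opt = np.linspace(-2.5, G + 2.5, n_species)
    y = np.exp(-((x[:, None] - opt[None, :]) ** 2) / (2 * tol**2)) * 50
    keep = y.sum(axis=0) > 1e-8
    return pd.DataFrame(
        y[:, keep],
        index=[f"S{i}" for i in range(n_sites)],
        columns=[f"sp{j}" for j in np.where(keep)[0]],
    )


def random_species_env(seed, n=20, p=8, m=4):
    rng = np.random.default_rng(seed)
    y = pd.DataFrame(rng.lognormal(1, 1, (n, p)),
                     index=[f"s{i}" for i in range(n)],
                     columns=[f"t{j}" for j in range(p)])
    x = pd.DataFrame(rng.normal(size=(n, m)), index=y.index,
                     columns=["temperature", "salinity",
                              "dissolved_oxygen", "pH"][:m])
    return y, x


# ---------------------------------------------------------------------------
# DCA


def test_identical_stations_axis_length_zero():
    two = pd.DataFrame([[1.0, 2.0, 3.0]] * 2, index=["a", "b"],
                       columns=["x", "y", "z"])
    res = DCA(two).fit()
    assert res.first_axis_length == pytest.approx(0.0)


def test_zero_row_and_column_rejected():
    bad = pd.DataFrame([[1.0, 0.0], [2.0, 0.0]], index=["a", "b"],
                       columns=["x", "dead"])
    with pytest.raises(ValidationError, match="dead"):
        DCA(bad)
    bad2 = pd.DataFrame([[1.0, 2.0], [0.0, 0.0]], index=["a", "empty"],
                        columns=["x", "y"])
    with pytest.raises(ValidationError, match="empty"):
        DCA(bad2)


def test_coenocline_gradient_length_recovered():
    """A 4-SD coenocline yields a first-axis length within 25% of 4."""
    res = DCA(coenocline(4.0)).fit()
    assert abs(res.first_axis_length - 4.0) <= 1.0


def test_short_gradient_fires_linear_gate():
    """A 1.5-SD gradient stays below the length-3 gate, so the pipeline
    proceeds with linear (RDA) ordination."""
    res = DCA(coenocline(1.5)).fit()
    assert res.first_axis_length < 3.0
    assert res.gate()


def test_undetrended_unrescaled_first_axis_is_ca():
    """Detrending/rescaling leave axis 1 of a plain run equal to the CA
    first axis (independent oracle: scikit-bio's correspondence
    analysis)."""
    from skbio.stats.ordination import ca

    rng = np.random.default_rng(3)
    y = pd.DataFrame(rng.lognormal(0.5, 1, (15, 10)))
    mine = DCA(y, rescale=False, detrend=False).fit(n_axes=2)
    sk = ca(y)
    r = np.corrcoef(mine.site_scores["DCA1"], sk.samples.iloc[:, 0])[0, 1]
    assert abs(r) == pytest.approx(1.0, abs=1e-8)
    assert mine.eigenvalues[0] == pytest.approx(float(sk.eigvals.iloc[0]),
                                                abs=1e-8)


# ---------------------------------------------------------------------------
# RDA


def test_perfect_linear_fit_fully_constrained():
    rng = np.random.default_rng(1)
    x = pd.DataFrame(rng.normal(size=(15, 3)),
                     index=[f"s{i}" for i in range(15)],
                     columns=["temperature", "salinity", "pH"])
    beta = rng.normal(size=(3, 5))
    y = pd.DataFrame(x.to_numpy() @ beta + 10.0, index=x.index,
                     columns=[f"t{j}" for j in range(5)])
    res = RDA(y, x).fit()
    assert res.proportion_constrained == pytest.approx(1.0, abs=1e-10)
    assert np.allclose(res.site_scores.to_numpy(),
                       res.site_scores_wa.to_numpy(), atol=1e-8)


def test_env_spanning_species_space_gives_pca_eigenvalues():
    """Predictors spanning the species space: canonical eigenvalues equal
    the PCA eigenvalues of the (centred) species matrix."""
    y, _ = random_species_env(2, n=20, p=6)
    x = y.copy()
    x.columns = [f"v{j}" for j in range(6)]
    res = RDA(y, x).fit()
    yc = y.to_numpy() - y.to_numpy().mean(axis=0)
    pca = np.linalg.svd(yc, compute_uv=False) ** 2 / (len(y) - 1)
    assert np.allclose(res.eigenvalues.to_numpy(), pca[: len(res.eigenvalues)],
                       atol=1e-10)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_rda_matches_regression_eigendecomposition_oracle(seed):
    """Explicit oracle: OLS projection then eigendecomposition of the
    fitted cross-product, to 1e-8."""
    y, x = random_species_env(seed)
    res = RDA(y, x).fit()
    yc = y.to_numpy() - y.to_numpy().mean(axis=0)
    xs = (x.to_numpy() - x.to_numpy().mean(axis=0)) / x.to_numpy().std(
        axis=0, ddof=1)
    fit = xs @ np.linalg.solve(xs.T @ xs, xs.T @ yc)
    ev = np.sort(np.linalg.eigvalsh(fit.T @ fit / (len(y) - 1)))[::-1]
    got = res.eigenvalues.to_numpy()
    assert np.allclose(got, ev[: len(got)], atol=1e-8)
    total = yc.var(axis=0, ddof=1).sum()
    assert res.eigenvalues.sum() + res.residual_eigenvalues.sum() == (
        pytest.approx(total, rel=1e-8)
    )


def test_rda_matches_skbio():
    """Cross-check canonical eigenvalues against scikit-bio's RDA."""
    from skbio.stats.ordination import rda as sk_rda

    y, x = random_species_env(5)
    res = RDA(y, x).fit()
    xs = (x - x.mean()) / x.std(ddof=1)
    sk = sk_rda(y - y.mean(), xs)
    k = len(res.eigenvalues)
    # skbio reports the raw singular values of the fitted matrix
    sk_eig = sk.eigvals.to_numpy()[:k] ** 2 / (len(y) - 1)
    assert np.allclose(res.eigenvalues.to_numpy(), sk_eig, atol=1e-8)


def test_proportion_constrained_monotone_in_predictors():
    y, x = random_species_env(7)
    props = [
        RDA(y, x.iloc[:, :m]).fit().proportion_constrained
        for m in range(1, x.shape[1] + 1)
    ]
    assert all(b >= a - 1e-12 for a, b in zip(props, props[1:]))


def test_biplot_scores_are_correlations(default_survey):
    abund, env, _, _ = default_survey
    dom = ci.dominant_taxa(ci.dominance_table(abund), ra_threshold=2.0)
    res = RDA(abund.select_taxa(list(dom.index)).data, env.data).fit()
    assert (res.biplot_scores.abs() <= 1.0 + 1e-12).all().all()
    # sign convention: strongest species loading positive on every axis
    for k in res.species_scores.columns:
        col = res.species_scores[k]
        assert col.loc[col.abs().idxmax()] > 0


def test_collinear_predictors_rejected():
    y, x = random_species_env(8)
    x = x.copy()
    x["pH"] = 2.0 * x["temperature"]
    with pytest.raises(ValidationError, match="collinear"):
        RDA(y, x).fit()


def test_too_few_stations_rejected():
    y, x = random_species_env(9, n=5, p=3, m=4)
    with pytest.raises(ValidationError, match="more stations"):
        RDA(y, x)
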