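"""Ordination: detrended correspondence analysis and redundancy analysis.

The analysis chain mirrors common community-ecology practice: compute the
DCA first-axis gradient length (in SD units of species turnover); when it
is below 3 the species-environment relationship is treated as linear and
redundancy analysis (RDA) is applied.

DCA
    Correspondence-analysis axes are extracted by reciprocal averaging
    (two-way weighted averaging iterated to a fixed point, convergence
    tolerance 1e-10).  Axes beyond the first are detrended against each
    earlier axis by the method of segments: within each of ``segments``
    equal-width windows of the earlier axis the running-mean-smoothed
    window mean is subtracted.  With ``rescale`` enabled, axes are put on
    the species-turnover (SD) scale by iterative segment-wise rescaling:
    the axis is stretched locally by the inverse of the local within-site
    weighted dispersion of species scores, so that one axis unit
    corresponds to one SD of species turnover.  The axis length is the
    range of the rescaled site scores.

RDA
    Species columns are centred (optionally variance-scaled or
    Hellinger-transformed first); environmental predictors are
    standardised.  Canonical axes are the SVD of the least-squares fitted
    species matrix; eigenvalues use the 1/(n-1) convention so canonical
    plus residual eigenvalues sum to the total species variance.  Scores
    follow a correlation-biplot (scaling 2) convention; axis signs are
    fixed so each axis's largest-magnitude species loading is positive.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .datatypes import AbundanceMatrix, EnvTable
from .errors import ValidationError

_TOL = 1e-10
_MAX_ITER = 1000


# ---------------------------------------------------------------------------
# DCA


@dataclasses.dataclass(frozen=True)
class DCAResults:
    """Axis lengths (SD units when rescaled), scores, and iteration count."""

    axis_lengths: np.ndarray
    eigenvalues: np.ndarray
    site_scores: pd.DataFrame
    species_scores: pd.DataFrame
    iterations: int
    rescaled: bool
    detrended: bool

    @property
    def first_axis_length(self) -> float:
        return float(self.axis_lengths[0])

    def gate(self, threshold: float = 3.0) -> bool:
        """True when the gradient is short enough for linear ordination."""
        return self.first_axis_length < threshold

    def summary(self) -> str:
        lines = ["Detrended correspondence analysis"]
        for i, (l, e) in enumerate(zip(self.axis_lengths, self.eigenvalues)):
            lines.append(f"  axis {i + 1}: length {l:.3f}  eigenvalue {e:.4f}")
        verdict = "linear (RDA)" if self.gate() else "unimodal"
        lines.append(f"  first-axis length {self.first_axis_length:.3f} "
                     f"=> {verdict} methods")
        return "\n".join(lines)


def _weighted_center(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    return x - np.average(x, weights=w)


def _detrend_segments(
    x: np.ndarray, prev: np.ndarray, w: np.ndarray, segments: int
) -> np.ndarray:
    """Subtract the smoothed within-segment weighted mean of ``x`` along the
    previous axis ``prev``."""
    lo, hi = prev.min(), prev.max()
    if hi - lo <= 0:
        return _weighted_center(x, w)
    edges = np.linspace(lo, hi, segments + 1)
    bins = np.clip(np.digitize(prev, edges[1:-1]), 0, segments - 1)
    means = np.full(segments, np.nan)
    for b in range(segments):
        mask = bins == b
        if mask.any():
            means[b] = np.average(x[mask], weights=w[mask])
    means = (
        pd.Series(means).ffill().bfill().to_numpy()
    )
    kernel = np.array([0.25, 0.5, 0.25])
    padded = np.concatenate([means[:1], means, means[-1:]])
    smoothed = np.convolve(padded, kernel, mode="valid")
    return x - smoothed[bins]


class DCA:
    """Detrended correspondence analysis of an abundance matrix.

    Parameters
    ----------
    abund :
        Site x species abundance matrix (no all-zero rows or columns).
    segments :
        Number of detrending / rescaling windows (default 26).
    rescale :
        Apply Hill's nonlinear rescaling so axis lengths come out in SD
        units of species turnover.
    detrend :
        Detrend axes >= 2; with ``detrend=False`` (and ``rescale=False``)
        the run reduces to plain correspondence analysis.
    """

    def __init__(
        self,
        abund: AbundanceMatrix | pd.DataFrame,
        segments: int = 26,
        rescale: bool = True,
        detrend: bool = True,
        rescale_iterations: int = 4,
    ):
        data = abund.data if isinstance(abund, AbundanceMatrix) else abund
        y = data.to_numpy(dtype=float)
        if np.any(y < 0):
            raise ValidationError("DCA requires non-negative abundances")
        zero_rows = np.where(y.sum(axis=1) == 0)[0]
        if len(zero_rows):
            raise ValidationError(
                f"station {data.index[zero_rows[0]]!r} has zero total "
                "abundance; drop it before ordination"
            )
        zero_cols = np.where(y.sum(axis=0) == 0)[0]
        if len(zero_cols):
            raise ValidationError(
                f"taxon {data.columns[zero_cols[0]]!r} is absent everywhere; "
                "drop it before ordination"
            )
        self.data = data
        self.segments = int(segments)
        self.rescale = bool(rescale)
        self.detrend = bool(detrend)
        self.rescale_iterations = int(rescale_iterations)

    def fit(self, n_axes: int = 4) -> DCAResults:
        y = self.data.to_numpy(dtype=float)
        n, p = y.shape
        r = y.sum(axis=1)
        c = y.sum(axis=0)
        total = y.sum()

        site_axes: list[np.ndarray] = []  # unit-variance basis (orthogonalisation)
        site_coords: list[np.ndarray] = []  # reported (possibly rescaled) scores
        species_axes: list[np.ndarray] = []
        lengths: list[float] = []
        eigenvalues: list[float] = []
        iterations = 0

        for axis in range(n_axes):
            x = np.arange(n, dtype=float)
            x = _weighted_center(x, r)
            norm = np.sqrt(np.average(x**2, weights=r))
            x = x / norm if norm > 0 else x
            eig = 0.0
            for it in range(_MAX_ITER):
                u = (y.T @ x) / c
                x_new = (y @ u) / r
                if axis > 0:
                    if self.detrend:
                        for prev in site_axes:
                            x_new = _detrend_segments(
                                x_new, prev, r, self.segments
                            )
                    else:
                        for prev in site_axes:
                            proj = np.average(x_new * prev, weights=r)
                            x_new = x_new - proj * prev
                x_new = _weighted_center(x_new, r)
                norm = np.sqrt(np.average(x_new**2, weights=r))
                if norm < 1e-12:
                    eig = 0.0
                    x = np.zeros(n)
                    break
                eig = norm
                x_new = x_new / norm
                if np.max(np.abs(x_new - x)) < _TOL or np.max(
                    np.abs(x_new + x)
                ) < _TOL:
                    x = x_new
                    iterations = max(iterations, it + 1)
                    break
                x = x_new
            else:
                iterations = _MAX_ITER

            if eig == 0.0:
                site_axes.append(np.zeros(n))
                site_coords.append(np.zeros(n))
                species_axes.append(np.zeros(p))
                lengths.append(0.0)
                eigenvalues.append(0.0)
                continue

            u = (y.T @ x) / c  # species scores, WA of unit-variance sites
            x_wa = (y @ u) / r  # pure weighted-average site scores
            if self.rescale:
                x_r, u_r, length = _hill_rescale(
                    y, x_wa, u, r, self.segments, self.rescale_iterations
                )
            else:
                x_r, u_r = x, u
                length = float(x.max() - x.min())
            site_axes.append(x)  # orthogonalisation basis stays unrescaled
            site_coords.append(x_r)
            species_axes.append(u_r)
            lengths.append(length)
            eigenvalues.append(float(eig))

        axis_names = [f"DCA{i + 1}" for i in range(n_axes)]
        return DCAResults(
            axis_lengths=np.asarray(lengths),
            eigenvalues=np.asarray(eigenvalues),
            site_scores=pd.DataFrame(
                np.column_stack(site_coords), index=self.data.index,
                columns=axis_names,
            ),
            species_scores=pd.DataFrame(
                np.column_stack(species_axes), index=self.data.columns,
                columns=axis_names,
            ),
            iterations=iterations,
            rescaled=self.rescale,
            detrended=self.detrend,
        )


def _hill_rescale(
    y: np.ndarray,
    x_site: np.ndarray,
    u_species: np.ndarray,
    r: np.ndarray,
    segments: int,
    iterations: int,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Iterative segment-wise rescaling to the species-turnover scale.

    Locally stretches the axis by the inverse of the within-site weighted
    SD of species scores, so that the rescaled within-site dispersion is
    ~1 everywhere; returns (site scores, species scores, axis length).
    """
    x = x_site.astype(float).copy()
    u = u_species.astype(float).copy()
    total = r.sum()
    for _ in range(iterations):
        span = x.max() - x.min()
        if span <= 0:
            return x - x.min(), u - x.min(), 0.0
        # per-site weighted dispersion of species scores about the site score
        resid = u[None, :] - x[:, None]
        d2 = (y * resid**2).sum(axis=1) / np.maximum(y.sum(axis=1), 1e-300)
        edges = np.linspace(x.min(), x.max(), segments + 1)
        bins = np.clip(np.digitize(x, edges[1:-1]), 0, segments - 1)
        disp = np.full(segments, np.nan)
        for b in range(segments):
            mask = bins == b
            if mask.any():
                disp[b] = np.sqrt(
                    np.average(d2[mask], weights=r[mask])
                )
        disp = pd.Series(disp).ffill().bfill().to_numpy()
        if np.isnan(disp).all():
            return x - x.min(), u - x.min(), 0.0
        kernel = np.array([0.25, 0.5, 0.25])
        padded = np.concatenate([disp[:1], disp, disp[-1:]])
        disp = np.convolve(padded, kernel, mode="valid")
        disp = np.maximum(disp, 1e-8)
        widths = np.diff(edges)
        new_edges = np.concatenate([[0.0], np.cumsum(widths / disp)])
        x = np.interp(x, edges, new_edges)
        u = np.interp(np.clip(u, edges[0], edges[-1]), edges, new_edges)
    x0 = x.min()
    return x - x0, u - x0, float(x.max() - x.min())


def dca_axis_lengths(
    abund: AbundanceMatrix | pd.DataFrame,
    segments: int = 26,
    rescale: bool = True,
) -> DCAResults:
    """Functional wrapper: DCA axis lengths for the linear-methods gate."""
    return DCA(abund, segments=segments, rescale=rescale).fit()


# ---------------------------------------------------------------------------
# RDA


@dataclasses.dataclass(frozen=True)
class RDAResults:
    """Canonical and residual structure of a fitted redundancy analysis."""

    eigenvalues: pd.Series  # canonical, descending
    residual_eigenvalues: pd.Series
    total_variance: float
    proportion_constrained: float
    site_scores: pd.DataFrame  # linear-combination (lc) scores
    site_scores_wa: pd.DataFrame  # weighted-average (wa) scores
    species_scores: pd.DataFrame
    biplot_scores: pd.DataFrame  # env x axes correlations

    def summary(self) -> str:
        lines = [
            "Redundancy analysis",
            f"  total variance: {self.total_variance:.4f}",
            f"  proportion constrained: {self.proportion_constrained:.4f}",
            "  canonical eigenvalues: "
            + ", ".join(f"{v:.4f}" for v in self.eigenvalues),
            "  biplot scores (env x axis correlations):",
        ]
        lines.append(
            self.biplot_scores.to_string(float_format=lambda v: f"{v:.3f}")
        )
        return "\n".join(lines)


class RDA:
    """Redundancy analysis of species abundances on environmental
    predictors.

    Parameters
    ----------
    species :
        Site x species abundance table (typically the dominant taxa).
    env :
        Site x predictor table, aligned on stations.
    scale_species :
        Scale centred species columns to unit variance.
    hellinger :
        Apply the Hellinger transform (sqrt of row-relative abundance)
        before centring.
    """

    def __init__(
        self,
        species: AbundanceMatrix | pd.DataFrame,
        env: EnvTable | pd.DataFrame,
        scale_species: bool = False,
        hellinger: bool = False,
    ):
        sp = species.data if isinstance(species, AbundanceMatrix) else species
        ev = env.data if isinstance(env, EnvTable) else env
        if list(sp.index) != list(ev.index):
            ev = ev.reindex(sp.index)
            if ev.isna().any().any():
                raise ValidationError(
                    "species and environment tables must cover the same "
                    "stations"
                )
        n, m = sp.shape[0], ev.shape[1]
        if n <= m + 1:
            raise ValidationError(
                f"RDA needs more stations ({n}) than predictors + 1 ({m + 1})"
            )
        self.species = sp
        self.env = ev
        self.scale_species = scale_species
        self.hellinger = hellinger

    def fit(self) -> RDAResults:
        yraw = self.species.to_numpy(dtype=float)
        n = yraw.shape[0]
        if self.hellinger:
            row = yraw.sum(axis=1, keepdims=True)
            if np.any(row == 0):
                raise ValidationError(
                    "Hellinger transform undefined for all-zero stations"
                )
            yraw = np.sqrt(yraw / row)
        y = yraw - yraw.mean(axis=0)
        if self.scale_species:
            sd = y.std(axis=0, ddof=1)
            sd[sd == 0] = 1.0
            y = y / sd

        xraw = self.env.to_numpy(dtype=float)
        xsd = xraw.std(axis=0, ddof=1)
        if np.any(xsd == 0):
            j = int(np.where(xsd == 0)[0][0])
            raise ValidationError(
                f"predictor {self.env.columns[j]!r} is constant"
            )
        x = (xraw - xraw.mean(axis=0)) / xsd
        if np.linalg.cond(x) > 1e10:
            raise ValidationError(
                "predictors are collinear (condition number > 1e10); "
                "remove redundant variables"
            )

        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        fitted = x @ beta
        resid = y - fitted

        uu, s, vt = np.linalg.svd(fitted, full_matrices=False)
        keep = s > max(s[0], 1.0) * 1e-12 if len(s) else np.array([], bool)
        uu, s, vt = uu[:, keep], s[keep], vt[keep]
        # deterministic sign: largest-|.| species loading positive per axis
        for k in range(len(s)):
            j = int(np.argmax(np.abs(vt[k])))
            if vt[k, j] < 0:
                vt[k] *= -1.0
                uu[:, k] *= -1.0

        eig_can = s**2 / (n - 1)
        s_res = np.linalg.svd(resid, compute_uv=False)
        eig_res = s_res**2 / (n - 1)
        eig_res = eig_res[eig_res > max(eig_res[0] if len(eig_res) else 0, 1.0) * 1e-12]
        total = float(y.var(axis=0, ddof=1).sum())
        constrained = float(eig_can.sum())
        prop = constrained / total if total > 0 else 0.0

        can_names = [f"RDA{i + 1}" for i in range(len(s))]
        res_names = [f"PC{i + 1}" for i in range(len(eig_res))]
        sqrt_n1 = np.sqrt(n - 1)
        lc = uu * sqrt_n1  # unit-variance site scores per axis
        species_scores = vt.T * (s / sqrt_n1)  # covariance-preserving loadings
        wa = y @ vt.T / s * sqrt_n1 if len(s) else np.zeros((n, 0))
        biplot = np.zeros((x.shape[1], len(s)))
        for j in range(x.shape[1]):
            for k in range(len(s)):
                biplot[j, k] = np.corrcoef(x[:, j], lc[:, k])[0, 1]

        return RDAResults(
            eigenvalues=pd.Series(eig_can, index=can_names, name="eigenvalue"),
            residual_eigenvalues=pd.Series(
                eig_res, index=res_names, name="eigenvalue"
            ),
            total_variance=total,
            proportion_constrained=prop,
            site_scores=pd.DataFrame(lc, index=self.species.index,
                                     columns=can_names),
            site_scores_wa=pd.DataFrame(wa, index=self.species.index,
                                        columns=can_names),
            species_scores=pd.DataFrame(
                species_scores, index=self.species.columns, columns=can_names
            ),
            biplot_scores=pd.DataFrame(
                biplot, index=self.env.columns, columns=can_names
            ),
        )


def rda(
    species: AbundanceMatrix | pd.DataFrame,
    env: EnvTable | pd.DataFrame,
    scale_species: bool = False,
) -> RDAResults:
    """Functional wrapper around :class:`RDA`."""
    return RDA(species, env, scale_species=scale_species).fit()


def gate_and_rda(
    species: AbundanceMatrix | pd.DataFrame,
    env: EnvTable | pd.DataFrame,
    segments: int = 26,
    gate_threshold: float = 3.0,
    **rda_kwargs,
) -> tuple[DCAResults, RDAResults]:
    """Run the DCA gradient-length gate, warn when it exceeds the linear
    threshold, and proceed to RDA either way (the unimodal alternative is
    out of scope)."""
    dca = DCA(species, segments=segments).fit()
    if not dca.gate(gate_threshold):
        warnings.warn(
            f"first DCA axis length {dca.first_axis_length:.2f} >= "
            f"{gate_threshold}: gradient is long for linear ordination; "
            "RDA results may understate unimodal structure",
            stacklevel=2,
        )
    return dca, RDA(species, env, **rda_kwargs).fit()
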