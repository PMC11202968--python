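"""Specific bioelectrical impedance vector analysis (specific BIVA).

Whole-body bioimpedance measures resistance R and reactance Xc (ohm) at
50 kHz. Classic BIVA analyses the vector (R, Xc); *specific* BIVA first
multiplies both components by A/L — an estimated body transverse area A
(cm^2) over the conductor length L (cm) — yielding Rsp and Xcsp in ohm*cm,
which removes most of the dependence on body size and leaves composition.
The vector modulus is the (specific) impedivity Zsp = sqrt(Rsp^2 + Xcsp^2)
and the inclination is the phase angle PhA = atan(Xc/R) in degrees, which is
unchanged by the standardization because A/L cancels in the ratio.

Bivariate comparison follows the vector-analysis convention: tolerance
ellipses (50/75/95% of a reference population, chi-square radii), confidence
ellipses (95% region for a sample's bivariate mean, exact small-sample
F-based radius), two-sample Hotelling T^2 with its F transform, and the
pooled-covariance Mahalanobis distance between group means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "BodyGeometry", "BioVector", "ReferencePopulation", "EllipseSpec",
    "HotellingResult", "derive_geometry", "specific_vector",
    "tolerance_ellipse", "confidence_ellipse", "hotelling_two_sample",
    "mahalanobis_d_from_t2", "f_from_t2", "plot_tolerance",
    "plot_confidence_pair", "BivaError", "InsufficientSampleError",
]


class BivaError(Exception):
    pass


class InsufficientSampleError(BivaError):
    """Sample too small for the requested ellipse or test."""


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not (value > 0):
            raise BivaError(f"{name} must be positive, got {value}")


@dataclass(frozen=True)
class BodyGeometry:
    """Anthropometric quantities entering the specific standardization."""

    height_cm: float
    weight_kg: float
    arm_circ_cm: float
    waist_circ_cm: float
    calf_circ_cm: float
    bmi: float
    arm_area_cm2: float
    waist_area_cm2: float
    calf_area_cm2: float
    a_factor_cm2: float  # weighted transverse area A
    l_factor_cm: float   # conductor length L = height * 1.1

    @property
    def correction(self) -> float:
        """The A/L factor (cm) multiplying R and Xc."""
        return self.a_factor_cm2 / self.l_factor_cm


def derive_geometry(
    height_cm: float, weight_kg: float,
    arm_circ_cm: float, waist_circ_cm: float, calf_circ_cm: float,
) -> BodyGeometry:
    """Derive BMI and the A/L standardization factors from anthropometry.

    Each segment area is modelled as a circle from its circumference,
    C^2/(4*pi); the body transverse area is the weighted sum
    A = 0.45*arm + 0.10*waist + 0.45*calf, and the conductor length is
    L = height * 1.1 (hand-to-foot electrode path).
    """
    _require_positive(
        height_cm=height_cm, weight_kg=weight_kg, arm_circ_cm=arm_circ_cm,
        waist_circ_cm=waist_circ_cm, calf_circ_cm=calf_circ_cm,
    )
    area = lambda c: c * c / (4.0 * math.pi)
    arm, waist, calf = area(arm_circ_cm), area(waist_circ_cm), area(calf_circ_cm)
    return BodyGeometry(
        height_cm=height_cm, weight_kg=weight_kg, arm_circ_cm=arm_circ_cm,
        waist_circ_cm=waist_circ_cm, calf_circ_cm=calf_circ_cm,
        bmi=weight_kg / (height_cm / 100.0) ** 2,
        arm_area_cm2=arm, waist_area_cm2=waist, calf_area_cm2=calf,
        a_factor_cm2=0.45 * arm + 0.10 * waist + 0.45 * calf,
        l_factor_cm=height_cm * 1.1,
    )


@dataclass(frozen=True)
class BioVector:
    """Raw and specific-standardized bioelectrical quantities."""

    r: float      # ohm
    xc: float     # ohm
    z: float      # ohm
    pha: float    # degrees
    rsp: float    # ohm*cm
    xcsp: float   # ohm*cm
    zsp: float    # ohm*cm


def specific_vector(r: float, xc: float, geometry: BodyGeometry) -> BioVector:
    """Standardize one (R, Xc) measurement by the subject's A/L factor."""
    _require_positive(r=r, xc=xc)
    k = geometry.correction
    rsp, xcsp = r * k, xc * k
    return BioVector(
        r=r, xc=xc,
        z=math.hypot(r, xc),
        pha=math.degrees(math.atan2(xc, r)),
        rsp=rsp, xcsp=xcsp, zsp=math.hypot(rsp, xcsp),
    )


@dataclass(frozen=True)
class ReferencePopulation:
    """Published bivariate (Rsp, Xcsp) summary of a reference population."""

    name: str
    n: int
    mean_rsp: float
    mean_xcsp: float
    sd_rsp: float
    sd_xcsp: float
    corr: float

    def __post_init__(self) -> None:
        if self.n < 3:
            raise BivaError(f"reference n must be >= 3, got {self.n}")
        _require_positive(sd_rsp=self.sd_rsp, sd_xcsp=self.sd_xcsp)
        if not -1.0 < self.corr < 1.0:
            raise BivaError(f"correlation must be in (-1, 1), got {self.corr}")

    @property
    def covariance(self) -> np.ndarray:
        off = self.corr * self.sd_rsp * self.sd_xcsp
        return np.array(
            [[self.sd_rsp ** 2, off], [off, self.sd_xcsp ** 2]]
        )


@dataclass(frozen=True)
class EllipseSpec:
    """A bivariate ellipse: center, shape matrix, and squared Mahalanobis
    radius. Points with squared Mahalanobis distance <= radius2 are inside
    (closed boundary)."""

    center: tuple
    covariance: np.ndarray
    radius2: float
    kind: str

    def __post_init__(self) -> None:
        cov = np.asarray(self.covariance, dtype=float)
        if cov.shape != (2, 2) or not np.allclose(cov, cov.T):
            raise BivaError("covariance must be symmetric 2x2")
        eigvals = np.linalg.eigvalsh(cov)
        if eigvals.min() <= 0:
            raise BivaError("covariance must be positive-definite")
        if not self.radius2 > 0:
            raise BivaError("radius2 must be positive")
        object.__setattr__(self, "covariance", cov)

    def mahalanobis2(self, point) -> float:
        d = np.asarray(point, dtype=float) - np.asarray(self.center, dtype=float)
        return float(d @ np.linalg.solve(self.covariance, d))

    def contains(self, point) -> bool:
        # closed boundary, with a relative epsilon so points constructed to
        # lie exactly on the perimeter are not lost to rounding
        return self.mahalanobis2(point) <= self.radius2 * (1.0 + 1e-12)

    def boundary(self, n_points: int = 200) -> np.ndarray:
        """(n_points x 2) polyline tracing the ellipse boundary."""
        theta = np.linspace(0.0, 2.0 * np.pi, n_points)
        circle = np.stack([np.cos(theta), np.sin(theta)])
        chol = np.linalg.cholesky(self.covariance)
        pts = (chol @ circle) * math.sqrt(self.radius2)
        return pts.T + np.asarray(self.center, dtype=float)

    @property
    def axes_lengths(self) -> tuple:
        """Semi-axis lengths (major, minor) in data units."""
        eigvals = np.linalg.eigvalsh(self.covariance)[::-1]
        return tuple(float(math.sqrt(e * self.radius2)) for e in eigvals)


_TOLERANCE_LEVELS = (0.50, 0.75, 0.95)


def tolerance_ellipse(ref: ReferencePopulation, coverage: float = 0.95) -> EllipseSpec:
    """Population tolerance ellipse containing the stated fraction of a
    bivariate-normal reference; the squared radius is the chi-square(2)
    quantile at the coverage level."""
    if not any(math.isclose(coverage, lv) for lv in _TOLERANCE_LEVELS):
        raise BivaError(
            f"coverage must be one of {_TOLERANCE_LEVELS}, got {coverage}"
        )
    return EllipseSpec(
        center=(ref.mean_rsp, ref.mean_xcsp),
        covariance=ref.covariance,
        radius2=float(stats.chi2.ppf(coverage, df=2)),
        kind=f"tolerance_{int(round(coverage * 100))}",
    )


def confidence_ellipse(sample, level: float = 0.95) -> EllipseSpec:
    """95% confidence ellipse for a sample's bivariate mean vector.

    The shape matrix is the sample covariance divided by n (the covariance of
    the mean) and the squared radius is the exact small-sample factor
    2*(n-1)/(n-2) * F(2, n-2; level).
    """
    x = np.asarray(sample, dtype=float)
    if x.ndim != 2 or x.shape[1] != 2:
        raise BivaError("sample must be (n x 2)")
    n = x.shape[0]
    if n < 4:
        raise InsufficientSampleError(f"need n >= 4 for a confidence ellipse, got {n}")
    cov = np.cov(x, rowvar=False, ddof=1)
    if np.linalg.det(cov) <= 0:
        raise BivaError("singular sample covariance (a coordinate has zero variance)")
    return EllipseSpec(
        center=tuple(x.mean(axis=0)),
        covariance=cov / n,
        radius2=float(2.0 * (n - 1) / (n - 2) * stats.f.ppf(level, 2, n - 2)),
        kind=f"confidence_{int(round(level * 100))}",
    )


@dataclass(frozen=True)
class HotellingResult:
    """Two-sample Hotelling comparison of bivariate mean vectors."""

    t2: float
    f_stat: float
    df: tuple
    p_value: float
    mahalanobis_d: float
    n1: int
    n2: int

    @property
    def significant(self) -> bool:
        """Non-overlap of the 95% confidence ellipses, read as p < 0.05."""
        return self.p_value < 0.05


def f_from_t2(t2: float, n_total: int) -> float:
    """F statistic for a bivariate two-sample T^2 with n_total subjects:
    F = T^2 * (n-3) / (2*(n-2)), on (2, n-3) degrees of freedom."""
    return t2 * (n_total - 3) / (2.0 * (n_total - 2))


def mahalanobis_d_from_t2(t2: float, n1: int, n2: int) -> float:
    """Pooled-covariance Mahalanobis distance between the two mean vectors,
    recovered from T^2: D = sqrt(T^2 * (n1+n2) / (n1*n2))."""
    return math.sqrt(t2 * (n1 + n2) / (n1 * n2))


def hotelling_two_sample(sample_a, sample_b) -> HotellingResult:
    """Two-sample Hotelling T^2 on bivariate (Rsp, Xcsp) samples.

    T^2 = (n1*n2/(n1+n2)) * d' S_pooled^-1 d with d the mean-vector
    difference and S_pooled the pooled sample covariance; the p-value comes
    from the exact F(2, n1+n2-3) reference distribution.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    for name, x in (("sample_a", a), ("sample_b", b)):
        if x.ndim != 2 or x.shape[1] != 2:
            raise BivaError(f"{name} must be (n x 2)")
        if x.shape[0] < 3:
            raise InsufficientSampleError(f"{name}: need n >= 3, got {x.shape[0]}")
    n1, n2 = a.shape[0], b.shape[0]
    s_pooled = (
        (n1 - 1) * np.cov(a, rowvar=False, ddof=1)
        + (n2 - 1) * np.cov(b, rowvar=False, ddof=1)
    ) / (n1 + n2 - 2)
    if np.linalg.det(s_pooled) <= 0:
        raise BivaError("singular pooled covariance")
    d = a.mean(axis=0) - b.mean(axis=0)
    t2 = float(n1 * n2 / (n1 + n2) * d @ np.linalg.solve(s_pooled, d))
    n = n1 + n2
    f_stat = f_from_t2(t2, n)
    p = float(stats.f.sf(f_stat, 2, n - 3))
    return HotellingResult(
        t2=t2, f_stat=float(f_stat), df=(2, n - 3), p_value=p,
        mahalanobis_d=mahalanobis_d_from_t2(t2, n1, n2), n1=n1, n2=n2,
    )


# ---------------------------------------------------------------------------
# Plotting (Rsp on x, Xcsp on y, ohm*cm, equal aspect)


def _setup_axes(ax, title: str | None):
    ax.set_xlabel("Rsp (ohm·cm)")
    ax.set_ylabel("Xcsp (ohm·cm)")
    ax.set_aspect("equal", adjustable="datalim")
    if title:
        ax.set_title(title)
    return ax


def plot_tolerance(
    ref: ReferencePopulation, points=None, labels=None, ax=None, title=None
):
    """Plot 50/75/95% tolerance ellipses of a reference with optional
    individual or mean vectors overlaid. Returns the matplotlib Axes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    for coverage, style in zip(_TOLERANCE_LEVELS, (":", "--", "-")):
        boundary = tolerance_ellipse(ref, coverage).boundary()
        ax.plot(boundary[:, 0], boundary[:, 1], style, color="gray",
                label=f"{int(coverage * 100)}% tolerance")
    if points is not None:
        pts = np.asarray(points, dtype=float)
        ax.scatter(pts[:, 0], pts[:, 1], s=18, zorder=3)
        if labels is not None:
            for (x, y), lab in zip(pts, labels):
                ax.annotate(str(lab), (x, y), fontsize=7)
    ax.legend(fontsize=8)
    return _setup_axes(ax, title or f"Reference: {ref.name}")


def plot_confidence_pair(samples: dict, ax=None, title=None):
    """Plot 95% confidence ellipses (mean + perimeter) for named samples."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    for name, sample in samples.items():
        spec = confidence_ellipse(np.asarray(sample, dtype=float))
        boundary = spec.boundary()
        line, = ax.plot(boundary[:, 0], boundary[:, 1], label=name)
        ax.plot(*spec.center, marker="o", color=line.get_color())
    ax.legend(fontsize=8)
    return _setup_axes(ax, title)
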