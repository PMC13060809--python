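"""Centroid tracks and tactic-fidelity metrics.

A simulated cell's centroid, sampled at a "microscopy" interval, yields step
vectors ``c_i``.  From these the classic directed-migration metrics follow:
net displacements ``Dx = sum c_{i,x}`` and ``Dy = sum c_{i,y}``, displacement
magnitude ``D = (Dx^2 + Dy^2)^(1/2)``, travel distance ``T = sum |c_i|``, the
forward migration indices along the gradient axes — Haptotactic Index
``HI = Dy / T`` and Chemotactic Index ``CI = Dx / T`` — and the persistence
ratio ``D / T`` (path straightness, in [0, 1]).  With the Cartesian
displacement angle ``theta = atan2(Dy, Dx)``, the decomposition
``HI = (D/T) sin(theta)``, ``CI = (D/T) cos(theta)`` holds identically.

Two angle conventions coexist in the directed-migration literature: the
Cartesian angle of the displacement vector (where the haptotactic +y axis
sits at +90 deg) and the angle measured from the gradient axis.  Both are
exported (``theta`` and ``theta_from_gradient``); neither is silently chosen.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Track",
    "MetricsResult",
    "WindRose",
    "centroid",
    "track_metrics",
    "wind_rose",
    "summarize",
]

#: physical scale: one dimensionless cell radius, in micrometers
RADIUS_UM = 20.0


@dataclass
class Track:
    """Ordered centroid samples ``(t, x, y)`` in domain units (cell radii)."""

    samples: np.ndarray
    radius_um: float = RADIUS_UM

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.samples.shape[1] != 3:
            raise ValueError("samples must be (t, x, y) triples")
        if np.any(np.diff(self.samples[:, 0]) <= 0):
            raise ValueError("sample times must be strictly increasing")

    @property
    def t(self) -> np.ndarray:
        return self.samples[:, 0]

    @property
    def xy(self) -> np.ndarray:
        return self.samples[:, 1:]

    def steps(self) -> np.ndarray:
        """Step vectors ``c_i`` between consecutive samples."""
        return np.diff(self.xy, axis=0)

    def resampled(self, interval: float) -> "Track":
        """Keep only samples on a coarser time grid (multiple of the cadence)."""
        t0 = self.t[0]
        rem = (self.t - t0) % interval
        keep = np.isclose(rem, 0.0) | np.isclose(rem, interval)
        return Track(self.samples[keep], self.radius_um)

    def to_dataframe(self):
        import pandas as pd

        df = pd.DataFrame(self.samples, columns=["t", "x", "y"])
        df["x_um"] = df.x * self.radius_um
        df["y_um"] = df.y * self.radius_um
        return df

    @classmethod
    def from_csv(cls, path, radius_um: float = RADIUS_UM) -> "Track":
        import pandas as pd

        df = pd.read_csv(path)
        return cls(df[["t", "x", "y"]].to_numpy(), radius_um)


@dataclass
class MetricsResult:
    """Directed-migration summary of one track."""

    Dx: float
    Dy: float
    D: float
    T: float
    HI: float
    CI: float
    persistence: float
    theta: float
    theta_from_gradient: float
    n_steps: int
    sampling_interval: float

    def to_dict(self) -> dict:
        return {
            "Dx": self.Dx, "Dy": self.Dy, "D": self.D, "T": self.T,
            "HI": self.HI, "CI": self.CI, "persistence": self.persistence,
            "theta": self.theta,
            "theta_from_gradient": self.theta_from_gradient,
            "n_steps": self.n_steps,
            "sampling_interval": self.sampling_interval,
        }


def centroid(phi: np.ndarray, mesh) -> tuple[float, float]:
    """Phase-field centroid ``(\\iint phi x dA, \\iint phi y dA) / \\iint phi dA``."""
    total = float(phi.sum())
    if total <= 0:
        raise ValueError("empty phase field has no centroid")
    X, Y = mesh.coords()
    return (float((phi * X).sum() / total), float((phi * Y).sum() / total))


def track_metrics(track: Track) -> MetricsResult:
    """Compute HI, CI, persistence, and displacement angles for one track.

    A degenerate track with zero travel distance returns zero indices with a
    warning (possible in very short scaled-down runs).
    """
    if len(track.samples) < 2:
        raise ValueError("a track needs at least 2 samples")
    c = track.steps()
    Dx, Dy = float(c[:, 0].sum()), float(c[:, 1].sum())
    D = float(np.hypot(Dx, Dy))
    T = float(np.hypot(c[:, 0], c[:, 1]).sum())
    if T == 0.0:
        warnings.warn("zero travel distance: indices defined as 0",
                      stacklevel=2)
        hi = ci = pers = theta = theta_g = 0.0
    else:
        hi, ci, pers = Dy / T, Dx / T, D / T
        theta = float(np.arctan2(Dy, Dx))
        # angle from the +y gradient axis, counterclockwise positive
        theta_g = float(np.arctan2(-Dx, Dy))
    dt_samp = float(np.median(np.diff(track.t)))
    return MetricsResult(Dx=Dx, Dy=Dy, D=D, T=T, HI=hi, CI=ci,
                         persistence=pers, theta=theta,
                         theta_from_gradient=theta_g,
                         n_steps=len(c), sampling_interval=dt_samp)


@dataclass
class WindRose:
    """Polar histogram of cumulative centroid displacement by step angle.

    ``bin_edges`` are Cartesian step angles in radians (the +y haptotactic
    axis sits at +pi/2); ``mass`` accumulates step magnitudes per bin, so the
    bin sums partition the total travel distance.
    """

    bin_edges: np.ndarray
    mass: np.ndarray
    per_track: np.ndarray | None = field(default=None)

    @property
    def total(self) -> float:
        return float(self.mass.sum())


def wind_rose(tracks, n_bins: int = 16, reference: str = "x") -> WindRose:
    """Accumulate step magnitudes into angular bins over one or more tracks.

    ``reference="x"`` bins Cartesian step angles ``atan2(cy, cx)`` over
    ``[-pi, pi)``; ``reference="gradient"`` measures angles from the +y
    gradient axis (counterclockwise positive) instead.
    """
    if n_bins < 4:
        raise ValueError("need at least 4 angular bins")
    if isinstance(tracks, Track):
        tracks = [tracks]
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    per_track = np.zeros((len(tracks), n_bins))
    for k, tr in enumerate(tracks):
        c = tr.steps()
        mag = np.hypot(c[:, 0], c[:, 1])
        nz = mag > 0
        if reference == "x":
            ang = np.arctan2(c[nz, 1], c[nz, 0])
        elif reference == "gradient":
            ang = np.arctan2(-c[nz, 0], c[nz, 1])
        else:
            raise ValueError(f"unknown reference {reference!r}")
        idx = np.clip(np.digitize(ang, edges) - 1, 0, n_bins - 1)
        np.add.at(per_track[k], idx, mag[nz])
    return WindRose(bin_edges=edges, mass=per_track.sum(axis=0),
                    per_track=per_track)


def summarize(values) -> tuple[float, float]:
    """Mean and half-width of the t-based 95% confidence interval."""
    from scipy import stats

    values = np.asarray(list(values), dtype=float)
    n = values.size
    if n < 2:
        raise ValueError("need at least 2 values to summarize")
    mean = float(values.mean())
    sem = float(values.std(ddof=1) / np.sqrt(n))
    half = float(stats.t.ppf(0.975, n - 1) * sem)
    return mean, half
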