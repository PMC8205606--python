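"""Spectral pretreatment operators and pipeline composition.

Implements the four pretreatment families compared in the study — Savitzky-
Golay first/second derivatives, SNV (standard normal variate) and MSC
(multiplicative scatter correction) — together with SG smoothing, per-
spectrum min-max normalization and PCA scores.

All operators act row-wise on an ``n x p`` matrix of spectra and are pure
apart from the MSC reference, which is fitted on training rows and frozen
when applied to test rows.  Derivatives are scaled by the grid step so they
carry units of reflectance/nm.

The default pipeline (SG window 59, polynomial order 2, first derivative,
valid mode, then min-max normalization) maps the 512-point acquisition grid
to the 454-point classifier input: 512 − (59 − 1) = 454.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter
from sklearn.decomposition import PCA

from .errors import DegenerateSpectrumError, ParameterError, PipelineError

__all__ = [
    "sg_filter",
    "snv",
    "MSCReference",
    "msc_fit",
    "msc_apply",
    "minmax_norm",
    "unit_norm",
    "trim",
    "PipelineStep",
    "PreprocessPipeline",
    "default_pipeline",
    "pca_scores",
]


def _as_matrix(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.ndim != 2:
        raise ParameterError(f"expected 1-D or 2-D input, got shape {X.shape}")
    return X


def sg_filter(
    X,
    window: int = 59,
    polyorder: int = 2,
    deriv_order: int = 0,
    mode: str = "same",
    step_nm: float = 1.0,
) -> np.ndarray:
    """Savitzky-Golay smoothing / derivative filter, applied per row.

    ``deriv_order`` 1 or 2 returns the first/second derivative divided by
    ``step_nm`` (units reflectance/nm).  ``mode='valid'`` keeps only points
    whose fitting window lies fully inside the spectrum, shortening each row
    by ``window - 1``; ``'same'`` pads by polynomial extrapolation at edges.
    """
    X = _as_matrix(X)
    p = X.shape[1]
    if window % 2 == 0:
        raise ParameterError(f"window must be odd, got {window}")
    if not (window > polyorder >= deriv_order >= 0):
        raise ParameterError(
            f"need window > polyorder >= deriv_order >= 0, got "
            f"window={window}, polyorder={polyorder}, deriv={deriv_order}"
        )
    if deriv_order > 2:
        raise ParameterError(f"deriv_order must be 0, 1 or 2, got {deriv_order}")
    if window > p:
        raise ParameterError(f"window {window} exceeds spectrum length {p}")
    if mode not in ("same", "valid"):
        raise ParameterError(f"mode must be 'same' or 'valid', got {mode!r}")
    out = savgol_filter(
        X, window_length=window, polyorder=polyorder, deriv=deriv_order,
        delta=step_nm, axis=1, mode="interp",
    )
    if mode == "valid":
        half = (window - 1) // 2
        out = out[:, half : p - half]
    return out


def snv(X, ddof: int = 1) -> np.ndarray:
    """Standard normal variate: center each row, divide by its sd.

    Removes additive offset and multiplicative scatter per spectrum.  The
    sample (n−1) standard deviation is the default; ``ddof=0`` selects the
    population form.
    """
    X = _as_matrix(X)
    sd = X.std(axis=1, ddof=ddof)
    bad = np.nonzero(sd <= 0)[0]
    if bad.size:
        raise DegenerateSpectrumError(f"constant spectrum at row {int(bad[0])}")
    return (X - X.mean(axis=1, keepdims=True)) / sd[:, None]


@dataclass(frozen=True)
class MSCReference:
    """Frozen MSC reference: the mean spectrum of the training rows."""

    reference_spectrum: np.ndarray


def msc_fit(X_train) -> MSCReference:
    """Fit the MSC reference (column mean) on training rows only."""
    X_train = _as_matrix(X_train)
    if X_train.shape[0] < 2:
        raise ParameterError("MSC needs >= 2 training rows to form a reference")
    return MSCReference(reference_spectrum=X_train.mean(axis=0))


def msc_apply(X, ref: MSCReference) -> np.ndarray:
    """Regress each row on the reference (x ≈ a + b·ref) and invert the fit.

    The corrected row is (x − a)/b, undoing per-spectrum additive and
    multiplicative scatter relative to the reference.
    """
    X = _as_matrix(X)
    r = np.asarray(ref.reference_spectrum, dtype=float)
    if X.shape[1] != r.size:
        raise ParameterError(
            f"row length {X.shape[1]} does not match reference length {r.size}"
        )
    rc = r - r.mean()
    denom = float(rc @ rc)
    if denom <= 0:
        raise DegenerateSpectrumError("MSC reference spectrum is constant")
    b = (X - X.mean(axis=1, keepdims=True)) @ rc / denom
    a = X.mean(axis=1) - b * r.mean()
    small = np.nonzero(np.abs(b) < 1e-12)[0]
    if small.size:
        raise DegenerateSpectrumError(
            f"row {int(small[0])} has near-zero slope against the reference; "
            "spectrum is not scatter-correctable"
        )
    return (X - a[:, None]) / b[:, None]


def minmax_norm(X) -> np.ndarray:
    """Affinely map each row onto [0, 1]."""
    X = _as_matrix(X)
    lo = X.min(axis=1, keepdims=True)
    hi = X.max(axis=1, keepdims=True)
    span = hi - lo
    bad = np.nonzero(span.ravel() <= 0)[0]
    if bad.size:
        raise DegenerateSpectrumError(f"constant spectrum at row {int(bad[0])}")
    return (X - lo) / span


def unit_norm(X) -> np.ndarray:
    """Scale each row to unit Euclidean norm (alternative normalization)."""
    X = _as_matrix(X)
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    bad = np.nonzero(norms.ravel() <= 0)[0]
    if bad.size:
        raise DegenerateSpectrumError(f"zero spectrum at row {int(bad[0])}")
    return X / norms


def trim(X, left: int = 0, right: int = 0) -> np.ndarray:
    """Drop ``left``/``right`` points from each end of every row."""
    X = _as_matrix(X)
    if left < 0 or right < 0 or left + right >= X.shape[1]:
        raise ParameterError(
            f"cannot trim {left}+{right} points from rows of length {X.shape[1]}"
        )
    return X[:, left : X.shape[1] - right or None]


@dataclass
class PipelineStep:
    name: str
    params: dict = field(default_factory=dict)


#: operator registry: name -> (stateless callable | None). MSC is stateful.
_STEP_NAMES = ("sg_smooth", "sg_derivative", "snv", "msc", "minmax_norm", "unit_norm", "trim")


class PreprocessPipeline:
    """Ordered, configured spectral operators with fit/transform semantics.

    Only MSC carries state (the training-mean reference); every other step
    is a pure row-wise map.  ``fit`` must be called on training rows before
    ``transform`` is applied to test rows when an ``msc`` step is present.
    """

    def __init__(self, steps: list[PipelineStep] | None = None, step_nm: float = 1.0):
        self.steps = list(steps or [])
        self.step_nm = step_nm
        self._msc_refs: dict[int, MSCReference] = {}
        for step in self.steps:
            if step.name not in _STEP_NAMES:
                raise ParameterError(
                    f"unknown step {step.name!r}; expected one of {', '.join(_STEP_NAMES)}"
                )

    # -- config round-trip ------------------------------------------------
    def to_config(self) -> dict:
        """Flat key-value form: ``steps`` plus ``<name>.<param>`` entries."""
        cfg: dict = {"steps": ",".join(s.name for s in self.steps)}
        for s in self.steps:
            for k, v in s.params.items():
                cfg[f"{s.name}.{k}"] = v
        return cfg

    @classmethod
    def from_config(cls, cfg: dict, step_nm: float = 1.0) -> "PreprocessPipeline":
        cfg = dict(cfg)
        names = [n.strip() for n in str(cfg.pop("steps", "")).split(",") if n.strip()]
        steps = []
        for name in names:
            prefix = name + "."
            params = {k[len(prefix):]: v for k, v in cfg.items() if k.startswith(prefix)}
            steps.append(PipelineStep(name, params))
        return cls(steps, step_nm=step_nm)

    # -- execution ---------------------------------------------------------
    def _run(self, X, fit: bool) -> np.ndarray:
        X = _as_matrix(X)
        for i, step in enumerate(self.steps):
            try:
                p = {k: v for k, v in step.params.items()}
                if step.name == "sg_smooth":
                    X = sg_filter(X, deriv_order=0, step_nm=self.step_nm,
                                  **{k: int(v) if k != "mode" else v for k, v in p.items()})
                elif step.name == "sg_derivative":
                    mode = p.pop("mode", "valid")
                    X = sg_filter(
                        X,
                        window=int(p.get("window", 59)),
                        polyorder=int(p.get("polyorder", 2)),
                        deriv_order=int(p.get("deriv", 1)),
                        mode=mode,
                        step_nm=self.step_nm,
                    )
                elif step.name == "snv":
                    X = snv(X, ddof=int(p.get("ddof", 1)))
                elif step.name == "msc":
                    if fit:
                        self._msc_refs[i] = msc_fit(X)
                    if i not in self._msc_refs:
                        raise PipelineError(
                            f"step {i} (msc): reference not fitted; call fit on training rows first"
                        )
                    X = msc_apply(X, self._msc_refs[i])
                elif step.name == "minmax_norm":
                    X = minmax_norm(X)
                elif step.name == "unit_norm":
                    X = unit_norm(X)
                elif step.name == "trim":
                    X = trim(X, left=int(p.get("left", 0)), right=int(p.get("right", 0)))
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"step {i} ({step.name}): {exc}") from exc
        return X

    def fit_transform(self, X_train) -> np.ndarray:
        """Fit any stateful steps on the training rows and transform them."""
        return self._run(X_train, fit=True)

    def transform(self, X) -> np.ndarray:
        """Apply the (already fitted) pipeline to new rows."""
        return self._run(X, fit=False)


def default_pipeline(step_nm: float = 3.125, window: int = 59, polyorder: int = 2,
                     deriv: int = 1) -> PreprocessPipeline:
    """SG first derivative (valid mode) then min-max normalization.

    On the 512-point acquisition grid the window-59 valid filter yields the
    454-point classifier input.
    """
    return PreprocessPipeline(
        [
            PipelineStep("sg_derivative",
                         {"window": window, "polyorder": polyorder, "deriv": deriv,
                          "mode": "valid"}),
            PipelineStep("minmax_norm"),
        ],
        step_nm=step_nm,
    )


def pca_scores(X, n_components: int):
    """Scores of column-mean-centered X on the leading principal axes.

    Returns ``(scores, explained_variance_ratio)``; ratios are sorted
    descending, each in [0, 1], summing to at most 1.  Columns are centered
    but not scaled — spectra share units.
    """
    X = _as_matrix(X)
    n, p = X.shape
    if not (1 <= n_components <= min(n - 1, p)):
        raise ParameterError(
            f"n_components must be in [1, {min(n - 1, p)}], got {n_components}"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    return scores, pca.explained_variance_ratio_
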