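"""Inverse Mie scattering with shallow dense networks.

The inverse problem — recover a sphere's radius a, refractive index m and
extinction coefficient kappa from its 1-D scattered-field representation —
is notoriously ill-conditioned (the direct linear system built from spherical
Hankel modes has condition numbers far beyond 1e20), so a trained network
serves as the regularised inverse.  Two networks with identical architecture
are compared throughout: one trained on the complex field (real and imaginary
channels) and one on the square root of its intensity, which differ exactly
by the phase information a holographic measurement adds.

The standard representation is the image-plane total field (incident
constant retained) on the near-uniform Bessel-zero radial grid: far-field
series -> optional aperture mask -> order-0 inverse DHT, L = 320 samples over
an 8 um half-field at lambda = 1 um.  Training corpora are full factorial
grids over (a, m, kappa), optionally crossed with a fourth sweep feature
(noise level, collection NA, or the separation of a second, identical
sphere).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import eval_legendre

from .hankel import HankelTransform
from .mie import Sphere, mie_coefficients
from .nn import DenseNetwork, TrainConfig

__all__ = [
    "MieDataset",
    "EvalReport",
    "InverseMieANN",
    "InverseMieResults",
    "DEFAULT_RANGES",
    "generate_dataset",
    "to_intensity",
    "split_dataset",
    "relative_rmse",
    "noise_sweep",
    "bandpass_sweep",
    "two_sphere_sweep",
]

DEFAULT_RANGES: Dict[str, Tuple[float, float]] = {
    "a": (1.0, 2.0),        # um
    "m": (1.1, 2.0),
    "kappa": (0.01, 0.05),
}
LABELS = ("a", "m", "kappa")


@dataclass
class MieDataset:
    """1-D field corpus with (a, m, kappa) labels.

    `inputs` is (N, L, 2): channel 0 real part, channel 1 imaginary part for
    complex datasets; for intensity datasets channel 0 holds sqrt(intensity)
    and channel 1 is zero.  `sweep_feature` optionally carries one extra
    per-sample value appended to the network input.
    """

    inputs: np.ndarray
    labels: np.ndarray
    representation: str
    radii: np.ndarray
    wavelength: float
    ranges: Dict[str, Tuple[float, float]]
    sweep_feature: Optional[np.ndarray] = None
    sweep_name: Optional[str] = None

    def __post_init__(self):
        self.inputs = np.asarray(self.inputs, float)
        self.labels = np.asarray(self.labels, float)
        if self.inputs.ndim != 3 or self.inputs.shape[2] != 2:
            raise ValueError("inputs must have shape (N, L, 2)")
        if self.labels.shape != (self.inputs.shape[0], 3):
            raise ValueError("labels must have shape (N, 3)")
        if self.representation not in ("complex", "intensity"):
            raise ValueError("representation must be 'complex' or 'intensity'")
        if self.representation == "intensity" and np.any(self.inputs[:, :, 0] < 0):
            raise ValueError("intensity channel must be nonnegative")
        for i, name in enumerate(LABELS):
            lo, hi = self.ranges[name]
            vals = self.labels[:, i]
            if vals.size and (vals.min() < lo - 1e-12 or vals.max() > hi + 1e-12):
                raise ValueError(f"label {name} outside declared range")
        if self.sweep_feature is not None:
            self.sweep_feature = np.asarray(self.sweep_feature, float)
            if self.sweep_feature.shape != (self.inputs.shape[0],):
                raise ValueError("sweep_feature must be one value per sample")

    @property
    def n_samples(self) -> int:
        return int(self.inputs.shape[0])

    def subset(self, idx) -> "MieDataset":
        return replace(
            self, inputs=self.inputs[idx], labels=self.labels[idx],
            sweep_feature=(None if self.sweep_feature is None
                           else self.sweep_feature[idx]))

    def network_inputs(self) -> np.ndarray:
        """Flattened (N, 2L [+1]) design matrix for the dense network."""
        flat = self.inputs.reshape(self.n_samples, -1)
        if self.sweep_feature is not None:
            flat = np.column_stack([flat, self.sweep_feature])
        return flat


def _factorial_labels(levels: int, ranges: Dict[str, Tuple[float, float]]):
    axes = [np.linspace(*ranges[name], levels) for name in LABELS]
    grids = np.meshgrid(*axes, indexing="ij")
    return np.column_stack([g.ravel() for g in grids])


def _far_field_matrix(labels: np.ndarray, wavelength: float,
                      v: np.ndarray) -> np.ndarray:
    """Far-field amplitude of every labelled sphere on radial frequencies v."""
    s = wavelength * v
    prop = s <= 1.0
    cos_t = np.sqrt(np.clip(1.0 - s[prop] ** 2, 0.0, 1.0))
    coeffs = []
    orders = 0
    for a, m, kap in labels:
        b = mie_coefficients(Sphere(a, m + 1j * kap), wavelength).coefficients
        coeffs.append(b)
        orders = max(orders, b.size)
    bmat = np.zeros((len(coeffs), orders), complex)
    for i, b in enumerate(coeffs):
        bmat[i, : b.size] = b * np.exp(-0.5j * np.pi * np.arange(b.size))
    legendre = np.stack([eval_legendre(t, cos_t) for t in range(orders)])
    far = np.zeros((len(coeffs), v.size), complex)
    far[:, prop] = bmat @ legendre
    return far


def generate_dataset(levels_per_feature: int,
                     ranges: Optional[Dict[str, Tuple[float, float]]] = None,
                     wavelength: float = 1.0, n_radial: int = 320,
                     r_max: float = 8.0) -> MieDataset:
    """Full factorial complex corpus: levels^3 spheres, 1-D spatial fields.

    Each label axis carries `levels_per_feature` uniformly spaced values in
    its range; each sample's input is the image-plane total field on the
    standard radial grid.  Pure function of its arguments (byte-identical
    across runs).
    """
    if levels_per_feature < 2:
        raise ValueError("need at least 2 levels per feature")
    ranges = dict(DEFAULT_RANGES if ranges is None else ranges)
    if ranges["m"][0] <= 1.0:
        raise ValueError("refractive-index range must stay above 1")
    labels = _factorial_labels(levels_per_feature, ranges)
    ht = HankelTransform(n_radial, r_max)
    far = _far_field_matrix(labels, wavelength, ht.v)
    spatial = (ht._inv @ far.T).T + 1.0          # incident DC retained
    inputs = np.stack([spatial.real, spatial.imag], axis=2)
    return MieDataset(inputs=inputs, labels=labels, representation="complex",
                      radii=ht.r.copy(), wavelength=wavelength, ranges=ranges)


def to_intensity(ds: MieDataset) -> MieDataset:
    """Square-root-intensity representation of a complex corpus.

    Channel 0 becomes sqrt(re^2 + im^2), channel 1 zero; labels, splits and
    sweep features are untouched.  A global phase rotation of a complex
    sample leaves its intensity representation unchanged — exactly the
    information a phase-sensitive measurement restores.
    """
    if ds.representation != "intensity" and ds.representation != "complex":
        raise ValueError("unknown representation")
    if ds.representation == "intensity":
        raise ValueError("dataset is already an intensity representation")
    mag = np.hypot(ds.inputs[:, :, 0], ds.inputs[:, :, 1])
    inputs = np.stack([mag, np.zeros_like(mag)], axis=2)
    return replace(ds, inputs=inputs, representation="intensity")


def split_dataset(ds: MieDataset, test_fraction: float = 0.1,
                  validation_fraction: float = 0.2, seed: int = 0):
    """Shuffle and split into (train, validation, test) datasets.

    `test_fraction` of the whole corpus is held out first; then
    `validation_fraction` of the remainder.  27 000 samples with the default
    fractions give 19 440 / 4 860 / 2 700.
    """
    n = ds.n_samples
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_test = int(round(n * test_fraction))
    test_idx = order[:n_test]
    rest = order[n_test:]
    n_val = int(round(rest.size * validation_fraction))
    val_idx = rest[:n_val]
    train_idx = rest[n_val:]
    return ds.subset(train_idx), ds.subset(val_idx), ds.subset(test_idx)


# ---------------------------------------------------------------------------
# evaluation metric
# ---------------------------------------------------------------------------

def relative_rmse(y_pred: np.ndarray, y_true: np.ndarray,
                  form: str = "printed") -> float:
    """Relative RMSE of one label, in percent.

    Two readings of the metric are supported:

    * ``"printed"``  : sqrt( mean( (y_pred - y_true)^2 / y_true ) )
    * ``"ratio"``    : sqrt( mean( ((y_pred - y_true) / y_true)^2 ) )

    Samples with a zero true value are excluded with a warning (the
    normalisation is undefined there).
    """
    y_pred = np.asarray(y_pred, float)
    y_true = np.asarray(y_true, float)
    ok = y_true != 0
    if not ok.all():
        warnings.warn("excluding samples with zero true label from the "
                      "relative RMSE", stacklevel=2)
    dp, dt = y_pred[ok], y_true[ok]
    if form == "printed":
        val = np.sqrt(np.mean((dp - dt) ** 2 / dt))
    elif form == "ratio":
        val = np.sqrt(np.mean(((dp - dt) / dt) ** 2))
    else:
        raise ValueError("form must be 'printed' or 'ratio'")
    return float(100.0 * val)


@dataclass
class EvalReport:
    """Per-label relative RMSE (%) of a trained model on a test set."""

    eps_printed: Dict[str, float]
    eps_ratio: Dict[str, float]
    n_test: int

    def combined(self, form: str = "ratio") -> float:
        d = self.eps_printed if form == "printed" else self.eps_ratio
        return float(np.mean([d[k] for k in LABELS]))

    def summary(self) -> str:
        lines = ["Relative RMSE (%) on held-out test set",
                 f"  n_test = {self.n_test}",
                 "  label    printed-form   ratio-form"]
        for k in ("m", "kappa", "a"):
            lines.append(f"  {k:<8} {self.eps_printed[k]:>10.2f}"
                         f"   {self.eps_ratio[k]:>10.2f}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class _InputScaler:
    """Per-feature z-score standardisation fitted on the training inputs.

    The 640-input dense layer trains unreliably on raw field values (some
    seeds fail to learn the refractive index at all); standardising each
    input feature stabilises every seed without changing the information
    content.
    """

    def __init__(self, x_train: np.ndarray):
        self.mu = x_train.mean(axis=0)
        sd = x_train.std(axis=0)
        sd[sd < 1e-12] = 1.0
        self.sd = sd

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (x - self.mu) / self.sd


class _KappaScaler:
    """Min-max map of the kappa label to [-1, 1], fitted on training labels."""

    def __init__(self, kappa_train: np.ndarray):
        self.lo = float(np.min(kappa_train))
        self.hi = float(np.max(kappa_train))
        if self.hi <= self.lo:
            self.hi = self.lo + 1.0

    def transform(self, labels: np.ndarray) -> np.ndarray:
        out = labels.copy()
        out[:, 2] = 2.0 * (out[:, 2] - self.lo) / (self.hi - self.lo) - 1.0
        return out

    def inverse(self, labels: np.ndarray) -> np.ndarray:
        out = labels.copy()
        out[:, 2] = self.lo + (out[:, 2] + 1.0) * (self.hi - self.lo) / 2.0
        return out


class InverseMieANN:
    """Model object: dense-network regression of (a, m, kappa) from 1-D fields.

    Parameters
    ----------
    train_set, val_set : MieDataset
        Training and validation splits (same representation).
    config : TrainConfig
        Training protocol; ``config.hidden`` sets the architecture
        (``(5,)`` is the shallow reference network, ``PRESETS['deep']`` a
        deeper variant).
    """

    def __init__(self, train_set: MieDataset, val_set: MieDataset,
                 config: Optional[TrainConfig] = None):
        if val_set.representation != train_set.representation:
            raise ValueError("train and validation representations differ")
        self.train_set = train_set
        self.val_set = val_set
        self.config = config or TrainConfig()

    def fit(self, seed: Optional[int] = None) -> "InverseMieResults":
        cfg = self.config
        seed = cfg.seed if seed is None else seed
        scaler = _KappaScaler(self.train_set.labels[:, 2])
        x_raw = self.train_set.network_inputs()
        in_scaler = _InputScaler(x_raw)
        x = in_scaler.transform(x_raw)
        y = scaler.transform(self.train_set.labels)
        xv = in_scaler.transform(self.val_set.network_inputs())
        yv = scaler.transform(self.val_set.labels)
        net = DenseNetwork([x.shape[1], *cfg.hidden, 3], seed=seed)
        net.fit(x, y, xv, yv, epochs=cfg.epochs, batch_size=cfg.batch_size,
                learning_rate=cfg.learning_rate, seed=seed + 1)
        return InverseMieResults(model=self, network=net, scaler=scaler,
                                 input_scaler=in_scaler, seed=seed)


@dataclass
class InverseMieResults:
    """A trained inverse-Mie network with its label scaling."""

    model: InverseMieANN
    network: DenseNetwork
    scaler: _KappaScaler
    input_scaler: "_InputScaler"
    seed: int

    def predict(self, ds: MieDataset) -> np.ndarray:
        """Predicted (a, m, kappa) on the physical scale."""
        raw = self.network.predict(
            self.input_scaler.transform(ds.network_inputs()))
        return self.scaler.inverse(raw)

    def evaluate(self, test_set: MieDataset) -> EvalReport:
        """Relative RMSE per label on a held-out set (kappa scaling inverted
        before the metric is computed)."""
        pred = self.predict(test_set)
        printed = {}
        ratio = {}
        for i, name in enumerate(LABELS):
            printed[name] = relative_rmse(pred[:, i], test_set.labels[:, i],
                                          "printed")
            ratio[name] = relative_rmse(pred[:, i], test_set.labels[:, i],
                                        "ratio")
        return EvalReport(eps_printed=printed, eps_ratio=ratio,
                          n_test=test_set.n_samples)

    def summary(self) -> str:
        hist = self.network.history
        lines = [
            "Inverse-Mie dense network",
            "=========================",
            f"representation : {self.model.train_set.representation}",
            f"architecture   : {self.network.layer_sizes}",
            f"seed           : {self.seed}",
            f"final train MSE: {hist['loss'][-1]:.3e}" if hist["loss"] else "",
        ]
        if hist["val_loss"]:
            lines.append(f"final val MSE  : {hist['val_loss'][-1]:.3e}")
        return "\n".join(l for l in lines if l)


# ---------------------------------------------------------------------------
# robustness sweeps
# ---------------------------------------------------------------------------

def _paired_eval(ds_complex: MieDataset, config: TrainConfig,
                 n_trials: int, seed: int, form: str) -> pd.DataFrame:
    """Train complex/intensity pairs and evaluate per sweep-feature value."""
    ds_intensity = to_intensity(ds_complex)
    rows = []
    for trial in range(n_trials):
        trial_seed = seed + 1000 * trial
        for ds, rep in ((ds_complex, "complex"), (ds_intensity, "intensity")):
            tr, va, te = split_dataset(ds, config.test_fraction,
                                       config.validation_fraction,
                                       seed=trial_seed)
            res = InverseMieANN(tr, va, config).fit(seed=trial_seed)
            pred = res.predict(te)
            sweep_vals = te.sweep_feature
            for val in np.unique(sweep_vals):
                sel = sweep_vals == val
                rec = {"sweep": float(val), "trial": trial,
                       "representation": rep, "n": int(sel.sum())}
                per = []
                for i, name in enumerate(LABELS):
                    e = relative_rmse(pred[sel, i], te.labels[sel, i], form)
                    rec[f"eps_{name}"] = e
                    per.append(e)
                rec["eps_mean"] = float(np.mean(per))
                rows.append(rec)
    return pd.DataFrame(rows)


def _with_sweep(ds: MieDataset, inputs: np.ndarray, feature: np.ndarray,
                labels: np.ndarray, name: str) -> MieDataset:
    return MieDataset(inputs=inputs, labels=labels, representation="complex",
                      radii=ds.radii, wavelength=ds.wavelength,
                      ranges=ds.ranges, sweep_feature=feature, sweep_name=name)


def noise_sweep(levels_per_feature: int = 10, n_noise_levels: int = 100,
                noise_range: Tuple[float, float] = (0.01, 1.00),
                config: Optional[TrainConfig] = None, n_trials: int = 1,
                seed: int = 0, form: str = "ratio",
                wavelength: float = 1.0) -> pd.DataFrame:
    """Gaussian-noise robustness sweep of the paired networks.

    The clean factorial corpus is replicated at `n_noise_levels` noise
    fractions; per channel, zero-mean Gaussian noise with standard deviation
    ``fraction * RMS(clean channel)`` is drawn independently for the real and
    imaginary parts, and the fraction joins the input as a fourth feature.
    Intensity inputs are computed from the *noisy* complex fields.
    """
    config = config or TrainConfig()
    base = generate_dataset(levels_per_feature, wavelength=wavelength)
    fracs = np.linspace(*noise_range, n_noise_levels)
    rng = np.random.default_rng(seed)
    blocks, feats, labs = [], [], []
    for frac in fracs:
        rms = np.sqrt(np.mean(base.inputs**2, axis=(1, 2), keepdims=True))
        noisy = base.inputs + rng.normal(size=base.inputs.shape) * (frac * rms)
        blocks.append(noisy)
        feats.append(np.full(base.n_samples, frac))
        labs.append(base.labels)
    ds = _with_sweep(base, np.concatenate(blocks), np.concatenate(feats),
                     np.concatenate(labs), "noise_fraction")
    return _paired_eval(ds, config, n_trials, seed, form)


def bandpass_sweep(levels_per_feature: int = 10, n_nas: int = 100,
                   na_range: Tuple[float, float] = (0.02, 1.01),
                   config: Optional[TrainConfig] = None, n_trials: int = 1,
                   seed: int = 0, form: str = "ratio",
                   wavelength: float = 1.0) -> pd.DataFrame:
    """Collection-aperture robustness sweep.

    Each corpus copy is band-limited by ``NA_out`` before the inverse DHT
    (NA joins the input as the fourth feature).  Apertures too small to
    retain any radial frequency sample are clamped to the first sample.
    """
    config = config or TrainConfig()
    ranges = dict(DEFAULT_RANGES)
    labels = _factorial_labels(levels_per_feature, ranges)
    ht = HankelTransform(320, 8.0)
    far = _far_field_matrix(labels, wavelength, ht.v)
    nas = np.linspace(*na_range, n_nas)
    blocks, feats, labs = [], [], []
    for na in nas:
        fu = na / wavelength
        mask = ht.v <= fu
        if not mask.any():
            mask = np.zeros_like(mask)
            mask[0] = True          # clamped to the first valid frequency
        spatial = (ht._inv @ (far * mask).T).T + 1.0
        blocks.append(np.stack([spatial.real, spatial.imag], axis=2))
        feats.append(np.full(labels.shape[0], na))
        labs.append(labels)
    base = MieDataset(inputs=blocks[0], labels=labels, representation="complex",
                      radii=ht.r.copy(), wavelength=wavelength, ranges=ranges)
    ds = _with_sweep(base, np.concatenate(blocks), np.concatenate(feats),
                     np.concatenate(labs), "na_out")
    return _paired_eval(ds, config, n_trials, seed, form)


def two_sphere_sweep(levels_per_feature: int = 10, n_distances: int = 100,
                     separation_range: Tuple[float, float] = (2.0, 8.0),
                     config: Optional[TrainConfig] = None, n_trials: int = 1,
                     seed: int = 0, form: str = "ratio",
                     wavelength: float = 1.0, fov: float = 16.0,
                     n_radial: int = 320) -> pd.DataFrame:
    """Structured-noise sweep: a second, identical sphere in the FOV.

    Both spheres share the (a, m, kappa) label; the central sphere stays at
    the origin while the perturbing sphere sits `separation` um away.  Inputs
    are the right-half line extractions through the central sphere
    (`n_radial` uniform samples over (0, fov/2]).  Separations smaller than
    the contact distance 2a are skipped for that label.
    """
    config = config or TrainConfig()
    ranges = dict(DEFAULT_RANGES)
    labels = _factorial_labels(levels_per_feature, ranges)
    seps = np.linspace(separation_range[1], separation_range[0], n_distances)
    xs = np.linspace(0.0, fov / 2.0, n_radial + 1)[1:]
    extent = fov / 2.0 + separation_range[1] + 2.0
    ht = HankelTransform(2048, extent)
    far = _far_field_matrix(labels, wavelength, ht.v)
    prof = (ht._inv @ far.T).T           # scattered-only radial profiles
    n_skipped = 0
    blocks, feats, labs = [], [], []
    for sep in seps:
        ok = 2.0 * labels[:, 0] <= sep
        if not ok.all():
            n_skipped += int((~ok).sum())
        sub = np.nonzero(ok)[0]
        if sub.size == 0:
            continue
        center = np.empty((sub.size, xs.size), complex)
        shifted = np.empty_like(center)
        for row, i in enumerate(sub):
            re = np.interp(xs, ht.r, prof[i].real)
            im = np.interp(xs, ht.r, prof[i].imag)
            center[row] = re + 1j * im
            re2 = np.interp(xs + sep, ht.r, prof[i].real)
            im2 = np.interp(xs + sep, ht.r, prof[i].imag)
            shifted[row] = re2 + 1j * im2
        g = 1.0 + center + shifted
        blocks.append(np.stack([g.real, g.imag], axis=2))
        feats.append(np.full(sub.size, sep))
        labs.append(labels[sub])
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} overlapping sphere/separation "
                      "combinations", stacklevel=2)
    base = MieDataset(inputs=blocks[0], labels=labs[0],
                      representation="complex", radii=xs, wavelength=wavelength,
                      ranges=ranges)
    ds = _with_sweep(base, np.concatenate(blocks), np.concatenate(feats),
                     np.concatenate(labs), "separation")
    return _paired_eval(ds, config, n_trials, seed, form)
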