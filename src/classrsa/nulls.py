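"""Surrogate time series and the permutation p-value.

Three surrogate constructions are provided for building permutation nulls on
hemodynamic time series:

- ``phase_randomize``: randomizes Fourier phases while preserving the
  amplitude spectrum (hence the autocorrelation), the conservative default
  for smooth hemodynamic signals;
- ``time_shuffle``: random permutation of samples (preserves the exact
  sample multiset, destroys all temporal structure);
- ``circular_shift``: random rotation of the series (preserves multiset and
  almost all autocorrelation structure).

The one-tailed permutation p is p = (1 + #{null >= empirical}) / (1 + n_perm),
which can never be zero.
"""

from __future__ import annotations

import numpy as np

from .types import ConfigError

METHODS = ("phase_randomize", "time_shuffle", "circular_shift")


def phase_randomize(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Fourier-phase surrogate with the same amplitude spectrum as ``x``."""
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    spec = np.fft.rfft(x, axis=-1)
    nf = spec.shape[-1]
    phases = rng.uniform(0, 2 * np.pi, size=spec.shape)
    phases[..., 0] = 0.0                      # DC stays real
    if n % 2 == 0:
        phases[..., nf - 1] = 0.0             # Nyquist stays real
    return np.fft.irfft(np.abs(spec) * np.exp(1j * phases), n=n, axis=-1)


def time_shuffle(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return x[..., rng.permutation(x.shape[-1])]


def circular_shift(x: np.ndarray, rng: np.random.Generator,
                   shift: int | None = None) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if shift is None:
        shift = int(rng.integers(0, x.shape[-1]))
    return np.roll(x, shift, axis=-1)


def surrogate(x: np.ndarray, method: str, rng: np.random.Generator) -> np.ndarray:
    if method == "phase_randomize":
        return phase_randomize(x, rng)
    if method == "time_shuffle":
        return time_shuffle(x, rng)
    if method == "circular_shift":
        return circular_shift(x, rng)
    raise ConfigError(f"unknown surrogate method {method!r}; "
                      f"choose one of {METHODS}")


def permutation_pvalue(empirical: float, null_values) -> float:
    """One-tailed p = (1 + #{null >= empirical}) / (1 + n_perm)."""
    null_values = np.asarray(null_values, dtype=float)
    return float((1 + np.sum(null_values >= empirical))
                 / (1 + null_values.size))


def circular_shift_offsets(n_samples: int, n_perm: int,
                           rng: np.random.Generator) -> np.ndarray:
    """Shift offsets for a circular-shift null on one series.

    Drawn without replacement while n_perm <= n_samples, so that asking for
    as many permutations as there are rotations reproduces the exhaustive
    null exactly; with replacement beyond that.
    """
    if n_perm <= n_samples:
        return rng.choice(n_samples, size=n_perm, replace=False)
    return rng.integers(0, n_samples, size=n_perm)


def null_distribution(x: np.ndarray, stat_fn, method: str, n_perm: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Null distribution of ``stat_fn(surrogate(x))`` for a single series.

    For ``circular_shift`` the offsets follow ``circular_shift_offsets``; an
    exhaustive null is obtained with ``n_perm == len(x)``.
    """
    if n_perm < 1:
        raise ConfigError("n_perm must be >= 1")
    x = np.asarray(x, dtype=float)
    if method == "circular_shift":
        offsets = circular_shift_offsets(x.shape[-1], n_perm, rng)
        return np.array([stat_fn(np.roll(x, int(s), axis=-1))
                         for s in offsets])
    return np.array([stat_fn(surrogate(x, method, rng))
                     for _ in range(n_perm)])
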