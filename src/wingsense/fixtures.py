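"""Synthetic fixtures for fast, simulation-free testing of the pipeline.

Three kinds are available:

``tiny-plate``
    A structurally valid wing on a coarse 5 x 10 element mesh, for solver
    tests that need seconds, not minutes.
``synthetic-spikes``
    First-spike matrices drawn from per-class Gaussians: every node shares
    the same latency mean within a class, the rotation class shifted by a
    stated amount.  With zero shift the two classes are statistically
    identical (a null dataset).
``separable-spikes``
    One informative node whose latency shifts between classes by much more
    than the trial noise; all other nodes are pure identical noise.  The
    informative node should dominate any sensible placement method.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .encoding import SpikeData
from .wing_model import WingSpec

__all__ = ["TinyPlate", "make_fixture"]

KINDS = ("tiny-plate", "synthetic-spikes", "separable-spikes")


@dataclass(frozen=True)
class TinyPlate:
    """Coarse-mesh wing specification for fast solver tests."""

    spec: WingSpec
    nx: int = 10
    ny: int = 5


def _quantize(t, bin_ms=0.1, period=40.0):
    """Clip latencies into (0, period] and snap to the encoding grid."""
    t = np.clip(t, bin_ms, period)
    return np.round(t / bin_ms) * bin_ms


def make_fixture(kind: str, seed: int = 0, **kwargs):
    """Build one of the named fixtures; deterministic in ``seed``."""
    if kind == "tiny-plate":
        return TinyPlate(spec=WingSpec(**kwargs))
    if kind == "synthetic-spikes":
        return _synthetic_spikes(seed, **kwargs)
    if kind == "separable-spikes":
        return _separable_spikes(seed, **kwargs)
    raise ValueError(f"unknown fixture kind '{kind}'; choose from {KINDS}")


def _synthetic_spikes(seed, n_nodes=60, n_trials=100, mean=20.0, jitter=1.0,
                      shift=0.0, period=40.0):
    """Gaussian latency matrices; ``shift`` moves the rotation class."""
    rng = np.random.default_rng(seed)
    flap = _quantize(rng.normal(mean, jitter, (n_trials, n_nodes)), period=period)
    rot = _quantize(rng.normal(mean + shift, jitter, (n_trials, n_nodes)),
                    period=period)
    return (SpikeData(first_spike=flap, wingbeat_period=period, class_label="flap"),
            SpikeData(first_spike=rot, wingbeat_period=period, class_label="rotation"))


def _separable_spikes(seed, n_nodes=60, n_trials=100, informative=7,
                      mean=20.0, noise=2.0, shift=5.0, info_jitter=0.2,
                      period=40.0):
    """One informative node (large latency shift), the rest identical noise."""
    rng = np.random.default_rng(seed)
    flap = rng.normal(mean, noise, (n_trials, n_nodes))
    rot = rng.normal(mean, noise, (n_trials, n_nodes))
    flap[:, informative] = rng.normal(mean, info_jitter, n_trials)
    rot[:, informative] = rng.normal(mean + shift, info_jitter, n_trials)
    return (SpikeData(first_spike=_quantize(flap, period=period),
                      wingbeat_period=period, class_label="flap"),
            SpikeData(first_spike=_quantize(rot, period=period),
                      wingbeat_period=period, class_label="rotation"))
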