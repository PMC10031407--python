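"""Rotation-detection accuracy of sensor subsets, and parameter sweeps.

The protocol mirrors the optimisation stage: 90% of the trials of each class
train the sensor placement and the final classifier, the held-out 10% score
it.  The classifier is a 1-D Fisher projection fitted on *non-standardised*
training latencies restricted to the selected sensors, with the decision
boundary at the midpoint of the two projected class centroids.

Placement sensitivity compares optimised against randomly placed sensors:
    sensitivity = acc_optimised / acc_random - 1,
0 meaning placement does not matter and 1 meaning optimised sensors are
perfect while random ones sit at chance.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import wing_model as wm
from .encoding import EncodingParams, SpikeData, encode_strain_field
from .placement import SensorSet, SSPOCParams, lda_direction, sspoc

__all__ = [
    "EvalResult", "SweepResult", "InvalidSplitError", "split_trials",
    "train_eval", "run_iteration", "random_sensor_accuracy",
    "placement_sensitivity", "spanwise_location_summary", "detection_run",
    "run_sweep",
]


class InvalidSplitError(ValueError):
    """Raised when a train/test split leaves a class empty."""


class UndefinedSensitivityError(ZeroDivisionError):
    """Raised when the random-placement accuracy is zero."""


@dataclass
class EvalResult:
    """Held-out classification outcome for one sensor set and split."""

    accuracy: float
    projection: np.ndarray        # per-test-trial scalar projections
    boundary: float               # midpoint decision threshold
    class_centroids: tuple        # (flap centroid, rotation centroid)
    sensor_set: SensorSet | None = None
    iteration_seed: int | None = None


@dataclass
class SweepResult:
    """Tidy per-iteration results of a structural parameter sweep."""

    table: pd.DataFrame
    failures: list = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        """Mean accuracy +/- SEM (and spanwise location) per sweep cell."""
        g = self.table.groupby(["E_mean", "gradient", "zeta", "axis"])
        out = g.agg(
            accuracy_mean=("accuracy", "mean"),
            accuracy_sem=("accuracy", "sem"),
            span_loc_mean=("span_loc", "mean"),
            span_loc_sem=("span_loc", "sem"),
            accuracy_random_mean=("accuracy_random", "mean"),
            n_iterations=("accuracy", "size"),
        ).reset_index()
        out["sensitivity"] = np.where(
            out["accuracy_random_mean"] > 0,
            out["accuracy_mean"] / out["accuracy_random_mean"] - 1.0,
            np.nan,
        )
        out["above_70pct"] = out["accuracy_mean"] > 0.70
        return out


# ---------------------------------------------------------------------------

def split_trials(n_trials: int, train_frac: float,
                 rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Random train/test partition of one class's trial indices."""
    n_train = int(round(train_frac * n_trials))
    if n_train < 2 or n_train >= n_trials:
        raise InvalidSplitError(
            f"train fraction {train_frac} leaves an unusable split of {n_trials}"
        )
    perm = rng.permutation(n_trials)
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def _fit_midpoint_classifier(train0, train1, ridge=1e-6):
    """1-D Fisher projection + midpoint boundary on raw latencies."""
    X = np.vstack([train0, train1])
    labels = np.concatenate([np.zeros(len(train0), bool), np.ones(len(train1), bool)])
    w_c = lda_direction(X, labels, ridge=ridge)
    c0 = float((train0 @ w_c).mean())
    c1 = float((train1 @ w_c).mean())
    boundary = 0.5 * (c0 + c1)
    return w_c, boundary, (c0, c1)


def train_eval(spikes_flap: SpikeData, spikes_rot: SpikeData,
               sensors: SensorSet,
               split: tuple | None = None,
               split_seed: int | None = None,
               train_frac: float = 0.9) -> EvalResult:
    """Held-out accuracy of a sensor subset under the midpoint classifier.

    ``split`` is ((train_flap, test_flap), (train_rot, test_rot)) index
    arrays; when omitted it is drawn from ``split_seed``.  The sensor set is
    expected to have been optimised on the same training trials only.
    """
    if split is None:
        rng = np.random.default_rng(split_seed)
        split = (split_trials(spikes_flap.n_trials, train_frac, rng),
                 split_trials(spikes_rot.n_trials, train_frac, rng))
    (tr0, te0), (tr1, te1) = split
    if len(te0) == 0 or len(te1) == 0:
        raise InvalidSplitError("empty test class")

    sel = sensors.selected
    F = spikes_flap.first_spike[:, sel]
    R = spikes_rot.first_spike[:, sel]
    w_c, boundary, centroids = _fit_midpoint_classifier(F[tr0], R[tr1])

    proj = np.concatenate([F[te0] @ w_c, R[te1] @ w_c])
    truth = np.concatenate([np.zeros(len(te0), bool), np.ones(len(te1), bool)])
    # rotation projects positive (lda_direction orientation), so the
    # rotation side of the boundary is the upper side
    pred = proj > boundary
    accuracy = float((pred == truth).mean())
    return EvalResult(accuracy=accuracy, projection=proj, boundary=boundary,
                      class_centroids=centroids, sensor_set=sensors,
                      iteration_seed=split_seed)


def run_iteration(spikes_flap: SpikeData, spikes_rot: SpikeData,
                  params: SSPOCParams, seed: int,
                  locations: np.ndarray | None = None
                  ) -> tuple[SensorSet, EvalResult]:
    """One optimisation iteration: split, optimise on train, score on test."""
    rng = np.random.default_rng(seed)
    split = (split_trials(spikes_flap.n_trials, params.train_frac, rng),
             split_trials(spikes_rot.n_trials, params.train_frac, rng))
    (tr0, _), (tr1, _) = split
    sensors = sspoc(spikes_flap.first_spike[tr0], spikes_rot.first_spike[tr1],
                    params, locations=locations)
    result = train_eval(spikes_flap, spikes_rot, sensors, split=split)
    result.iteration_seed = seed
    return sensors, result


def random_sensor_accuracy(spikes_flap: SpikeData, spikes_rot: SpikeData,
                           n_sensors: int, n_draws: int,
                           rng: np.random.Generator,
                           train_frac: float = 0.9) -> float:
    """Mean held-out accuracy over random sensor subsets (fresh split each)."""
    n_nodes = spikes_flap.n_nodes
    accs = []
    for _ in range(n_draws):
        sel = np.sort(rng.choice(n_nodes, size=n_sensors, replace=False))
        sensors = SensorSet(weights=np.zeros(n_nodes), selected=sel)
        split = (split_trials(spikes_flap.n_trials, train_frac, rng),
                 split_trials(spikes_rot.n_trials, train_frac, rng))
        try:
            accs.append(train_eval(spikes_flap, spikes_rot, sensors,
                                   split=split).accuracy)
        except Exception:           # degenerate subsets count as chance
            accs.append(0.5)
    return float(np.mean(accs))


def placement_sensitivity(acc_opt: float, acc_rand: float) -> float:
    """Accuracy ratio of optimised to random sensors, minus one."""
    if acc_rand <= 0:
        raise UndefinedSensitivityError("random-placement accuracy is zero")
    return acc_opt / acc_rand - 1.0


def spanwise_location_summary(sensor_sets, span: float):
    """Mean normalised spanwise sensor position and its SEM over iterations.

    Positions are x / span in [0, 1] from wing base to tip, pooled over the
    sensors of each iteration; the SEM is computed across iteration means.
    """
    sets = list(sensor_sets)
    if not sets:
        raise ValueError("need at least one sensor set")
    per_iter = []
    for ss in sets:
        if ss.locations is None:
            raise ValueError("sensor sets must carry grid locations")
        per_iter.append(np.mean(ss.locations[:, 0]) / span)
    per_iter = np.asarray(per_iter)
    mean = float(per_iter.mean())
    sem = float(per_iter.std(ddof=1) / np.sqrt(len(per_iter))) if len(per_iter) > 1 else 0.0
    return mean, sem


# ---------------------------------------------------------------------------
# full pipeline runs
# ---------------------------------------------------------------------------

def detection_run(spec: wm.WingSpec, axis: str,
                  enc: EncodingParams | None = None,
                  sspoc_params: SSPOCParams | None = None,
                  seed: int = 0, n_iterations: int | None = None,
                  n_random: int = 0, nx: int = 50, ny: int = 25,
                  dt: float = 2e-4, n_cycles: int | None = None,
                  kin_kwargs: dict | None = None) -> pd.DataFrame:
    """Simulate, encode and evaluate one wing/rotation condition.

    Each iteration redraws the spike-generation stream and the 90/10 split;
    the strain fields are simulated once (they are deterministic).  Returns
    one row per iteration with the accuracy, mean spanwise sensor location
    and, if ``n_random`` > 0, the random-placement baseline accuracy.
    """
    enc = enc or EncodingParams()
    sspoc_params = sspoc_params or SSPOCParams()
    n_iter = n_iterations or sspoc_params.n_iterations
    kin_kwargs = kin_kwargs or {}

    kin_flap = wm.Kinematics(rotation_axis="none", **kin_kwargs)
    kin_rot = wm.Kinematics(rotation_axis=axis, **kin_kwargs)
    flap = wm.simulate_strain(spec, kin_flap, dt=dt, nx=nx, ny=ny, n_cycles=n_cycles)
    # both conditions run the same number of wingbeats so any residual
    # transient is common mode and cancels in the class difference
    n_shared = n_cycles or flap.provenance["cycles_run"]
    rot = wm.simulate_strain(spec, kin_rot, dt=dt, nx=nx, ny=ny, n_cycles=n_shared)
    locations = np.column_stack([flap.X, flap.Y])

    ss = np.random.SeedSequence(seed)
    rows = []
    for it in range(n_iter):
        enc_seed_f, enc_seed_r, it_seed, rnd_seed = [
            int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)
        ]
        spikes_f = encode_strain_field(flap, enc, rng=enc_seed_f)
        spikes_r = encode_strain_field(rot, enc, rng=enc_seed_r)
        sensors, res = run_iteration(spikes_f, spikes_r, sspoc_params,
                                     seed=it_seed, locations=locations)
        row = {
            "iteration": it, "accuracy": res.accuracy,
            "span_loc": float(np.mean(sensors.locations[:, 0]) / spec.span),
            "accuracy_random": np.nan,
        }
        if n_random > 0:
            rng = np.random.default_rng(rnd_seed)
            row["accuracy_random"] = random_sensor_accuracy(
                spikes_f, spikes_r, sspoc_params.n_sensors, n_random, rng,
                train_frac=sspoc_params.train_frac)
        rows.append(row)
    return pd.DataFrame(rows)


def run_sweep(E_grid, gradients, zetas, axes, spec_base: wm.WingSpec | None = None,
              enc: EncodingParams | None = None,
              sspoc_params: SSPOCParams | None = None,
              seed: int = 0, n_iterations: int | None = None,
              n_random: int = 20, nx: int = 50, ny: int = 25,
              dt: float = 2e-4, n_cycles: int | None = None) -> SweepResult:
    """Grid sweep over mean stiffness, gradient flag, damping and axis.

    Executes simulate -> encode -> place -> evaluate for every cell and
    iteration.  Stage errors are recorded per cell and the sweep continues.
    """
    spec_base = spec_base or wm.WingSpec()
    frames, failures = [], []
    for ci, (E, grad, zeta, axis) in enumerate(
            itertools.product(E_grid, gradients, zetas, axes)):
        spec = wm.WingSpec(
            span=spec_base.span, chord=spec_base.chord,
            thickness=spec_base.thickness, density=spec_base.density,
            poisson=spec_base.poisson, E_mean=E, gradient=grad,
            decline_x=spec_base.decline_x, decline_y=spec_base.decline_y,
            zeta=zeta)
        try:
            df = detection_run(spec, axis, enc=enc, sspoc_params=sspoc_params,
                               seed=seed + 104729 * ci,
                               n_iterations=n_iterations, n_random=n_random,
                               nx=nx, ny=ny, dt=dt, n_cycles=n_cycles)
        except Exception as exc:
            failures.append({"E_mean": E, "gradient": grad, "zeta": zeta,
                             "axis": axis, "error": repr(exc)})
            warnings.warn(f"sweep cell failed ({E:g}, {grad}, {zeta}, {axis}): {exc}")
            continue
        df["E_mean"] = E
        df["gradient"] = grad
        df["zeta"] = zeta
        df["axis"] = axis
        frames.append(df)
    table = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    return SweepResult(table=table, failures=failures)


def default_stiffness_grid(n: int = 9) -> np.ndarray:
    """Log-spaced mean moduli spanning two orders of magnitude around 3 GPa."""
    return np.geomspace(0.3e9, 30e9, n)
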