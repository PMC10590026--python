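"""Expectation–maximisation binary clustering (EMbC) of trajectories.

A 4-component bivariate Gaussian mixture on (speed, |turning angle|) whose
components are labelled by where their means fall relative to per-variable
delimiters, giving the four behavioural states used throughout the
pipeline:

====================  ==========  ===========
state                 speed       |turn|
====================  ==========  ===========
stopped               low         high
floating              low         low
commuting             high        low
foraging_searching    high        high
====================  ==========  ===========

The mixture itself is fitted with scikit-learn's EM (one iteration per
warm-started call so the log-likelihood trace is available and its
monotonicity checkable); the delimiter construction, quadrant labelling and
bout extraction on top are what make it a behavioural annotator.  Runs of
fixes labelled stopped or floating are the on-water bouts that anchor the
pressure calibration and are excluded from flight-height analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from sklearn.cluster import kmeans_plusplus
from sklearn.mixture import GaussianMixture

STATE_OF_QUADRANT = {
    # (high speed?, high turn?) -> state
    (False, True): "stopped",
    (False, False): "floating",
    (True, False): "commuting",
    (True, True): "foraging_searching",
}

WATER_STATES = ("stopped", "floating")

VARIANCE_FLOOR = 1e-6


class DegenerateFitError(RuntimeError):
    """EM collapsed or the components do not occupy the four quadrants."""


@dataclass
class EmbcModel:
    weights: np.ndarray  # (4,)
    means: np.ndarray  # (4, 2): speed m/s, |turn| rad
    covariances: np.ndarray  # (4, 2, 2)
    speed_delimiter: float
    turn_delimiter: float
    label_map: dict[int, str]  # component index -> state
    n_iter: int = 0
    log_likelihood_trace: list[float] = dc_field(default_factory=list)
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "covariances": self.covariances.tolist(),
            "speed_delimiter": self.speed_delimiter,
            "turn_delimiter": self.turn_delimiter,
            "label_map": {int(k): v for k, v in self.label_map.items()},
            "n_iter": self.n_iter,
            "log_likelihood": self.log_likelihood_trace[-1] if self.log_likelihood_trace else None,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EmbcModel":
        return cls(
            weights=np.asarray(d["weights"]),
            means=np.asarray(d["means"]),
            covariances=np.asarray(d["covariances"]),
            speed_delimiter=float(d["speed_delimiter"]),
            turn_delimiter=float(d["turn_delimiter"]),
            label_map={int(k): v for k, v in d["label_map"].items()},
            n_iter=int(d.get("n_iter", 0)),
            seed=d.get("seed"),
        )

    def posteriors(self, speeds, abs_turns) -> np.ndarray:
        gm = self._as_sklearn()
        X = np.column_stack([np.asarray(speeds, float), np.asarray(abs_turns, float)])
        return gm.predict_proba(X)

    def _as_sklearn(self) -> GaussianMixture:
        gm = GaussianMixture(n_components=4, covariance_type="full")
        gm.weights_ = self.weights
        gm.means_ = self.means
        gm.covariances_ = self.covariances
        gm.precisions_cholesky_ = _precisions_cholesky(self.covariances)
        return gm


def _precisions_cholesky(covs: np.ndarray) -> np.ndarray:
    # sklearn's convention: transpose-inverse of the covariance Cholesky factor
    out = np.empty_like(covs)
    for i, c in enumerate(covs):
        out[i] = np.linalg.inv(np.linalg.cholesky(c)).T
    return out


def _delimiters(means: np.ndarray) -> tuple[float, float]:
    """Per-variable midpoint between the two low and the two high component means."""
    delims = []
    for j in range(2):
        vals = np.sort(means[:, j])
        delims.append(0.5 * (vals[1] + vals[2]))
    return float(delims[0]), float(delims[1])


def _label_components(means: np.ndarray) -> dict[int, str]:
    sd, td = _delimiters(means)
    label_map: dict[int, str] = {}
    for i, (ms, mt) in enumerate(means):
        label_map[i] = STATE_OF_QUADRANT[(ms > sd, mt > td)]
    if len(set(label_map.values())) != 4:
        raise DegenerateFitError("component means do not occupy the four quadrants")
    return label_map


def fit_embc(
    speeds,
    abs_turns,
    max_iter: int = 300,
    tol: float = 1e-6,
    seed: int = 0,
    max_restarts: int = 5,
) -> EmbcModel:
    """Fit the 4-state mixture to (speed, |turn|) pairs.

    EM runs one iteration at a time so the per-iteration log-likelihood is
    recorded; convergence is declared when the change drops below ``tol``
    (per-sample average log-likelihood) or ``max_iter`` is reached.
    Collapsed components or a non-bijective quadrant labelling trigger a
    restart with a fresh seed, at most ``max_restarts`` times.
    """
    speeds = np.asarray(speeds, dtype=float)
    abs_turns = np.asarray(abs_turns, dtype=float)
    if len(speeds) < 100:
        raise ValueError("need at least 100 points to fit the mixture")
    if not (np.all(np.isfinite(speeds)) and np.all(np.isfinite(abs_turns))):
        raise ValueError("speeds and turns must be finite")
    if np.any(speeds < 0) or np.any(abs_turns < 0):
        raise ValueError("speeds and |turns| must be non-negative")
    X = np.column_stack([speeds, abs_turns])
    # a quadrant labelling is meaningless unless each variable really has a
    # low and a high mode; restarting cannot fix inseparable data
    for j, varname in enumerate(("speed", "turn")):
        if not _is_bimodal(X[:, j], seed):
            raise DegenerateFitError(f"no low/high separation on {varname}")

    last_err: Exception | None = None
    for attempt in range(max_restarts + 1):
        attempt_seed = seed + attempt
        try:
            return _fit_once(X, max_iter, tol, attempt_seed)
        except DegenerateFitError as err:
            last_err = err
    raise DegenerateFitError(
        f"EM degenerate after {max_restarts} restarts: {last_err}"
    )


def _is_bimodal(x: np.ndarray, seed: int, bic_margin: float = 10.0) -> bool:
    X = x.reshape(-1, 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        g1 = GaussianMixture(1, random_state=seed).fit(X)
        g2 = GaussianMixture(2, random_state=seed, n_init=3).fit(X)
    return g1.bic(X) - g2.bic(X) > bic_margin


def _fit_once(X: np.ndarray, max_iter: int, tol: float, seed: int) -> EmbcModel:
    # k-means++ seeding on standardized variables for determinism
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    centers, _ = kmeans_plusplus(X / scale, n_clusters=4, random_state=seed)
    gm = GaussianMixture(
        n_components=4,
        covariance_type="full",
        reg_covar=VARIANCE_FLOOR,
        means_init=centers * scale,
        max_iter=1,
        warm_start=True,
        tol=0.0,
        random_state=seed,
    )
    trace: list[float] = []
    for it in range(max_iter):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gm.fit(X)
        trace.append(float(gm.lower_bound_))
        if len(trace) >= 2 and abs(trace[-1] - trace[-2]) < tol:
            break

    weights = gm.weights_.copy()
    means = gm.means_.copy()
    covs = gm.covariances_.copy()
    if np.any(weights < 1e-3):
        raise DegenerateFitError("component weight collapsed below 1e-3")
    eigs = np.linalg.eigvalsh(covs)
    if np.any(eigs < VARIANCE_FLOOR / 2):
        raise DegenerateFitError("covariance eigenvalue below the variance floor")
    label_map = _label_components(means)
    sd, td = _delimiters(means)
    return EmbcModel(
        weights=weights,
        means=means,
        covariances=covs,
        speed_delimiter=sd,
        turn_delimiter=td,
        label_map=label_map,
        n_iter=len(trace),
        log_likelihood_trace=trace,
        seed=seed,
    )


def classify_states(model: EmbcModel, speeds, abs_turns) -> pd.DataFrame:
    """Maximum-posterior state per point.

    Ties go to the lower component index (the order of ``model.means``).
    Returns a frame with ``state`` and ``posterior`` columns.
    """
    speeds = np.asarray(speeds, dtype=float)
    abs_turns = np.asarray(abs_turns, dtype=float)
    if not (np.all(np.isfinite(speeds)) and np.all(np.isfinite(abs_turns))):
        raise ValueError("non-finite values in classification input")
    post = model.posteriors(speeds, abs_turns)
    comp = np.argmax(post, axis=1)  # first max -> lowest index on ties
    states = np.array([model.label_map[int(c)] for c in comp])
    return pd.DataFrame({"state": states, "posterior": post[np.arange(len(comp)), comp]})


def floating_bouts(
    labels,
    timestamps,
    individual_ids=None,
    index=None,
) -> pd.DataFrame:
    """Maximal runs of consecutive stopped/floating fixes, per individual.

    Returns a frame with ``bout_id``, ``individual_id``, ``start``, ``end``,
    ``mid`` and ``fix_index`` (the labels' index values of member fixes).
    Empty input yields an empty frame.
    """
    labels = np.asarray(labels)
    ts = pd.DatetimeIndex(timestamps)
    n = len(labels)
    if individual_ids is None:
        individual_ids = np.array(["_all"] * n)
    else:
        individual_ids = np.asarray(individual_ids).astype(str)
    if index is None:
        index = np.arange(n)
    else:
        index = np.asarray(index)

    cols = {"bout_id": [], "individual_id": [], "start": [], "end": [], "mid": [], "fix_index": []}
    if n == 0:
        return pd.DataFrame(cols)

    on_water = np.isin(labels, WATER_STATES)
    new_ind = np.r_[True, individual_ids[1:] != individual_ids[:-1]]
    run_break = np.r_[True, on_water[1:] != on_water[:-1]] | new_ind
    run_id = np.cumsum(run_break)

    bout_id = 0
    for rid in np.unique(run_id):
        sel = run_id == rid
        if not on_water[sel][0]:
            continue
        idx = np.flatnonzero(sel)
        start, end = ts[idx[0]], ts[idx[-1]]
        cols["bout_id"].append(bout_id)
        cols["individual_id"].append(individual_ids[idx[0]])
        cols["start"].append(start)
        cols["end"].append(end)
        cols["mid"].append(start + (end - start) / 2)
        cols["fix_index"].append(list(index[idx]))
        bout_id += 1
    return pd.DataFrame(cols)
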