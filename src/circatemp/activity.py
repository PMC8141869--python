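"""Three-state hidden Markov decoding of chest accelerometry.

Minute activity counts are modelled as a homogeneous 3-state Gaussian HMM
— inactive/rest (IA), intermediately active (MA) and highly active (HA) —
fitted by Baum–Welch with random restarts.  Emissions are Gaussian on the
raw count scale by default; a log1p option exists for strongly
right-skewed real-world counts (near-zero rest counts make the log scale
badly non-Gaussian, so raw is the safer default).  States are always
relabelled by ascending emission mean so IA < MA < HA regardless of EM
initialisation.

Decoding is retrospective and probabilistic: the smoothed posterior state
probabilities are computed for every observed minute and the hard path is
the per-minute posterior mode.  The scalar summary used downstream is the
*activity strength*: the median of the raw activity values decoded as MA
or HA (intermediate-to-high activity).

Missing minutes are excluded by splitting the record into contiguous
observed segments (each an independent chain in the likelihood); they get
no decoded state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from hmmlearn.hmm import GaussianHMM

from .series import MinuteSeries

STATE_NAMES = ("IA", "MA", "HA")


@dataclass
class ActivityHMM:
    """Fitted 3-state activity model with decoded path and posteriors.

    ``means``/``sds`` are on the observation scale actually fitted
    (log1p-transformed if ``log_scale``); ``path`` holds −1 at missing
    minutes and ``posterior`` rows are NaN there.
    """

    means: np.ndarray  # ascending: IA < MA < HA
    sds: np.ndarray
    transition_matrix: np.ndarray
    initial_distribution: np.ndarray
    log_likelihood: float
    path: np.ndarray  # per-minute state index, -1 = missing
    posterior: np.ndarray  # (n, 3), rows sum to 1 at observed minutes
    log_scale: bool

    def state_name(self, idx: int) -> str:
        return STATE_NAMES[idx]


def _segments(mask_ok: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [i, j) runs of consecutive observed minutes."""
    runs = []
    i = 0
    n = len(mask_ok)
    while i < n:
        if mask_ok[i]:
            j = i
            while j < n and mask_ok[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def fit_activity_hmm(
    series: MinuteSeries,
    n_states: int = 3,
    n_restarts: int = 3,
    seed: int | None = None,
    log_scale: bool = False,
    n_iter: int = 100,
) -> ActivityHMM:
    """Fit the activity HMM by EM, best of ``n_restarts`` by log-likelihood.

    Requires at least 24 h of data; a (near-)constant series is degenerate
    and rejected.  States are relabelled by ascending emission mean, with
    ties broken by transition persistence (larger self-transition first).
    Deterministic given ``seed``.
    """
    if series.channel != "activity":
        raise ValueError(f"expected the activity channel, got {series.channel!r}")
    if series.span_hours < 24:
        raise ValueError("HMM fitting requires at least 24 h of data")
    if seed is None:
        raise ValueError("a seed is required for reproducible EM restarts")
    ok = ~series.missing
    x = series.values[ok]
    if np.std(x) < 1e-12:
        raise ValueError("degenerate (constant) activity series")
    obs = np.log1p(x) if log_scale else x
    obs = obs.reshape(-1, 1)
    runs = _segments(ok)
    lengths = [j - i for i, j in runs]

    best = None
    root = np.random.SeedSequence(seed)
    for child in root.spawn(n_restarts):
        model = GaussianHMM(
            n_components=n_states,
            covariance_type="diag",
            n_iter=n_iter,
            random_state=np.random.RandomState(int(child.generate_state(1)[0] % 2**31)),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(obs, lengths)
            ll = model.score(obs, lengths)
        if best is None or ll > best[0]:
            best = (ll, model)
    ll, model = best

    means = model.means_.ravel()
    sds = np.sqrt(np.array([model.covars_[k].ravel()[0] for k in range(n_states)]))
    # relabel ascending by mean; tie-break toward the more persistent state
    order = np.lexsort((-np.diag(model.transmat_), means))
    if np.any(np.diff(means[order]) == 0):
        warnings.warn("tied emission means: relabeling broken by persistence", stacklevel=2)
    inv = np.empty(n_states, dtype=int)
    inv[order] = np.arange(n_states)

    post_obs = model.predict_proba(obs, lengths)[:, order]
    n = len(series)
    posterior = np.full((n, n_states), np.nan)
    posterior[ok] = post_obs
    path = np.full(n, -1, dtype=int)
    path[ok] = np.argmax(post_obs, axis=1)

    return ActivityHMM(
        means=means[order],
        sds=sds[order],
        transition_matrix=model.transmat_[np.ix_(order, order)],
        initial_distribution=model.startprob_[order],
        log_likelihood=float(ll),
        path=path,
        posterior=posterior,
        log_scale=log_scale,
    )


def activity_strength(fit: ActivityHMM, series: MinuteSeries) -> float | None:
    """Median raw activity over minutes decoded as MA or HA.

    Summarises each subject's intermediate-to-high activity level in
    accelerations/min.  Returns ``None`` (with a warning) if no minute was
    decoded as MA or HA.
    """
    sel = (fit.path >= 1) & ~series.missing
    if not np.any(sel):
        warnings.warn("no MA/HA minutes decoded: activity strength undefined", stacklevel=2)
        return None
    return float(np.median(series.values[sel]))
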