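"""ON/OFF state classification, cell-file coherence, and the cis/trans test.

A vernalized meristem contains a mixture of cells with the reporter stably
ON and stably OFF, visible as a bimodal distribution of per-cell mean
intensities.  States are called by fitting a two-component Gaussian mixture
to log mean intensities, guarded by a unimodality check: the population is
treated as single-state unless a two-component model is supported by BIC,
has component means separated by at least one pooled standard deviation,
and the modes differ by a biologically meaningful factor (0.5 log-units,
i.e. >= 1.65-fold, by default — ON/OFF reporter contrast is several-fold,
while sub-structure within one state is far smaller).  The extra guards are
needed because a two-component maximum likelihood fit to genuinely unimodal
data still splits it into two overlapping components 1-2 SD apart.

The two-reporter cis/trans test formalises the four-state argument: under
trans memory every cell file is ON/ON or OFF/OFF and mixed-state files can
arise only from per-cell call error, so the observed fraction of
mixed-state files is compared against a parametric bootstrap of that null.
A two-sided exact binomial test additionally checks the symmetry of the
ON/OFF vs OFF/ON counts expected under cis memory.  Both statistics are
constructions of this package (the original argument was qualitative).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binomtest
from sklearn.mixture import GaussianMixture

ON = "ON"
OFF = "OFF"

#: default absolute intensity threshold (a.u.) used only when a population
#: is judged unimodal and must be assigned a single state; should sit
#: between the typical OFF and ON per-cell means of the calibration in use
DEFAULT_FALLBACK_THRESHOLD = 25.0

#: minimum distance between mixture modes, in log-intensity units, for a
#: population to be called bimodal (0.5 ~= a 1.65-fold intensity ratio)
DEFAULT_MIN_MODE_SEPARATION = 0.5


@dataclass
class ClassifyInfo:
    """Diagnostics of one classification run."""

    bimodal: bool
    component_means: np.ndarray  # log-intensity means, ascending
    component_sds: np.ndarray
    weights: np.ndarray
    separation_sds: float
    on_fraction: float


@dataclass
class StateCall:
    cell_id: int
    states: dict[str, str]
    margin: float  # posterior margin |p(ON) - p(OFF)| (1.0 on unimodal path)


def classify_states(
    values: np.ndarray,
    fallback_threshold: float = DEFAULT_FALLBACK_THRESHOLD,
    min_mode_separation: float = DEFAULT_MIN_MODE_SEPARATION,
    random_state: int = 0,
) -> tuple[np.ndarray, np.ndarray, ClassifyInfo]:
    """Call each cell ON or OFF from its mean intensity.

    Fits a two-component Gaussian mixture to log intensities and assigns
    each cell to the component with higher posterior probability (upper
    component = ON).  If the fit is not supported (BIC prefers one
    component, or component means are separated by less than one pooled SD),
    the population is declared unimodal and every cell receives the single
    state given by comparing the population median against the absolute
    ``fallback_threshold``.

    Returns ``(states, margins, info)`` with states as "ON"/"OFF" strings.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1:
        raise ValueError("values must be 1-D")
    if len(values) < 20:
        raise ValueError("state classification needs at least 20 cells")
    x = np.log(np.clip(values, 1e-9, None))[:, None]

    bimodal = False
    if np.ptp(x) > 0:
        gm1 = GaussianMixture(1, random_state=random_state).fit(x)
        gm2 = GaussianMixture(2, random_state=random_state, n_init=3).fit(x)
        mu = gm2.means_.ravel()
        sd = np.sqrt(gm2.covariances_.ravel())
        w = gm2.weights_.ravel()
        order = np.argsort(mu)
        mu, sd, w = mu[order], sd[order], w[order]
        pooled_sd = float(np.sqrt(np.sum(w * sd**2)))
        separation = abs(mu[1] - mu[0]) / pooled_sd if pooled_sd > 0 else np.inf
        bimodal = (
            gm2.bic(x) < gm1.bic(x)
            and separation >= 1.0
            and abs(mu[1] - mu[0]) >= min_mode_separation
        )
    else:
        mu = np.array([x[0, 0], x[0, 0]])
        sd = np.zeros(2)
        w = np.array([1.0, 0.0])
        separation = 0.0

    if bimodal:
        post = gm2.predict_proba(x)[:, order]
        p_on = post[:, 1]
        states = np.where(p_on >= 0.5, ON, OFF)
        margins = np.abs(2.0 * p_on - 1.0)
        on_fraction = float((states == ON).mean())
    else:
        state = ON if float(np.median(values)) >= fallback_threshold else OFF
        states = np.full(len(values), state, dtype=object)
        margins = np.ones(len(values))
        on_fraction = 1.0 if state == ON else 0.0

    info = ClassifyInfo(
        bimodal=bool(bimodal),
        component_means=mu,
        component_sds=sd,
        weights=w,
        separation_sds=float(separation),
        on_fraction=on_fraction,
    )
    return np.asarray(states, dtype=object), margins, info


def call_states(
    table: pd.DataFrame,
    channels: list[str],
    fallback_threshold: float = DEFAULT_FALLBACK_THRESHOLD,
    random_state: int = 0,
) -> tuple[pd.DataFrame, dict[str, ClassifyInfo]]:
    """Add ``state_<channel>`` columns to a per-cell table of mean intensities.

    One channel is classified at a time from its ``mean_<channel>`` column.
    """
    out = table.copy()
    infos = {}
    for ch in channels:
        states, margins, info = classify_states(
            out[f"mean_{ch}"].to_numpy(),
            fallback_threshold=fallback_threshold,
            random_state=random_state,
        )
        out[f"state_{ch}"] = states
        out[f"margin_{ch}"] = margins
        infos[ch] = info
    return out, infos


@dataclass
class HistogramSummary:
    counts: np.ndarray
    bin_edges: np.ndarray
    bimodal: bool
    on_fraction: float


def histogram_summary(
    values: np.ndarray,
    bins: int = 30,
    fallback_threshold: float = DEFAULT_FALLBACK_THRESHOLD,
    random_state: int = 0,
) -> HistogramSummary:
    """Binned counts of per-cell mean intensity plus a bimodality decision."""
    values = np.asarray(values, dtype=float)
    counts, edges = np.histogram(values, bins=bins)
    _, _, info = classify_states(
        values, fallback_threshold=fallback_threshold, random_state=random_state
    )
    return HistogramSummary(
        counts=counts,
        bin_edges=edges,
        bimodal=info.bimodal,
        on_fraction=info.on_fraction,
    )


# ----------------------------------------------------------------------
@dataclass
class FileCoherence:
    """Run-length structure of state calls along clonal cell files.

    ``score`` is the mean, over files of length >= 2, of the fraction of
    cells agreeing with their file's majority state.  Under file-level
    generative states with per-cell call error e, the expected score is
    approximately 1 - e.
    """

    score: float
    per_file: pd.DataFrame
    run_lengths: list[int]


def file_coherence(
    table: pd.DataFrame,
    state_col: str = "state_reporter_1",
    file_col: str = "file_id",
    pos_col: str = "pos_in_file",
) -> FileCoherence:
    """Per-file run-length summaries and the overall coherence score."""
    rows = []
    runs_all: list[int] = []
    scores = []
    for fid, grp in table.groupby(file_col, sort=True):
        states = grp.sort_values(pos_col)[state_col].to_numpy()
        n = len(states)
        runs = []
        cur = 1
        for a, b in zip(states, states[1:]):
            if a == b:
                cur += 1
            else:
                runs.append(cur)
                cur = 1
        runs.append(cur)
        n_on = int((states == ON).sum())
        majority_fraction = max(n_on, n - n_on) / n
        rows.append(
            {
                "file_id": fid,
                "length": n,
                "n_on": n_on,
                "majority_fraction": majority_fraction,
                "n_runs": len(runs),
                "longest_run": max(runs),
            }
        )
        runs_all.extend(runs)
        if n >= 2:
            scores.append(majority_fraction)
    score = float(np.mean(scores)) if scores else np.nan
    return FileCoherence(
        score=score, per_file=pd.DataFrame(rows), run_lengths=runs_all
    )


# ----------------------------------------------------------------------
@dataclass
class CisTransResult:
    """Outcome of the two-reporter cis-vs-trans test (file level)."""

    n_files: int
    n_onon: int
    n_onoff: int
    n_offon: int
    n_offoff: int
    mixed_fraction: float
    p_value: float  # parametric bootstrap of the trans null
    p_symmetry: float  # exact two-sided binomial on (ON/OFF, OFF/ON)
    error_rate: float  # within-file discordance, the estimated call error
    p_on_hat: float  # ON/ON probability under the fitted trans null
    p_off_per_reporter: dict[str, float]


def _majority_on(n_on: np.ndarray, length: np.ndarray) -> np.ndarray:
    """File-level state: ON iff at least half the cells are called ON."""
    return 2 * n_on >= length


def cis_trans_test(
    table: pd.DataFrame,
    reporters: tuple[str, str] = ("reporter_1", "reporter_2"),
    file_col: str = "file_id",
    n_boot: int = 999,
    seed: int = 0,
) -> CisTransResult:
    """Test the trans-memory null on two-reporter state calls.

    Under trans memory each file is ON/ON or OFF/OFF; mixed-state files can
    arise only through per-cell call error, whose rate is estimated from
    within-file discordance.  The statistic is the observed fraction of
    mixed-state files; its null distribution comes from a parametric
    bootstrap (files drawn ON/ON with the fitted probability, i.i.d. call
    errors applied per cell, file states re-derived by majority).  The
    symmetry of the two mixed states, expected under cis memory, is
    assessed by an exact two-sided binomial test.
    """
    if len(reporters) != 2:
        raise ValueError("the cis/trans test requires exactly two reporters")
    cols = [f"state_{r}" for r in reporters]
    for c in cols:
        if c not in table.columns:
            raise ValueError(f"missing state column {c!r}")
    grouped = table.groupby(file_col, sort=True)
    lengths = grouped.size().to_numpy()
    n_files = len(lengths)
    if n_files < 10:
        raise ValueError("the cis/trans test needs at least 10 files")

    n_on = np.stack(
        [grouped[c].apply(lambda s: int((s == ON).sum())).to_numpy() for c in cols],
        axis=1,
    )  # (files, 2)
    maj = _majority_on(n_on, lengths[:, None])  # (files, 2)
    onon = int((maj[:, 0] & maj[:, 1]).sum())
    onoff = int((maj[:, 0] & ~maj[:, 1]).sum())
    offon = int((~maj[:, 0] & maj[:, 1]).sum())
    offoff = int((~maj[:, 0] & ~maj[:, 1]).sum())
    mixed_obs = (onoff + offon) / n_files

    # call-error estimate: pooled within-file minority fraction
    minority = np.minimum(n_on, lengths[:, None] - n_on)
    error_rate = float(minority.sum() / (2 * lengths.sum()))
    p_on_hat = float((onon + 0.5 * (onoff + offon)) / n_files)

    rng = np.random.default_rng(seed)
    file_on = rng.random((n_boot, n_files)) < p_on_hat
    mixed_sim = np.zeros(n_boot)
    maj_sim = []
    for _ in range(2):
        flips = rng.binomial(lengths[None, :], error_rate, (n_boot, n_files))
        on_counts = np.where(file_on, lengths[None, :] - flips, flips)
        maj_sim.append(_majority_on(on_counts, lengths[None, :]))
    mixed_sim = (maj_sim[0] != maj_sim[1]).mean(axis=1)
    p_value = float((1 + (mixed_sim >= mixed_obs - 1e-12).sum()) / (n_boot + 1))

    n_mixed = onoff + offon
    p_symmetry = (
        float(binomtest(onoff, n_mixed, 0.5).pvalue) if n_mixed > 0 else 1.0
    )
    p_off = {
        r: float((~maj[:, i]).mean()) for i, r in enumerate(reporters)
    }
    return CisTransResult(
        n_files=n_files,
        n_onon=onon,
        n_onoff=onoff,
        n_offon=offon,
        n_offoff=offoff,
        mixed_fraction=mixed_obs,
        p_value=p_value,
        p_symmetry=p_symmetry,
        error_rate=error_rate,
        p_on_hat=p_on_hat,
        p_off_per_reporter=p_off,
    )
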