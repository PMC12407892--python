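"""Single-neuron selectivity to task variables.

Selectivity of a neuron to one binary task variable (stimulus side, choice
direction, or reward outcome) is quantified by the condition-combined
Mann-Whitney U statistic. Within each stratum j — a combination of fixed
values of the two *other* task variables — spike counts are ranked
(average ranks for ties) and

    U_j = min(R1 - n1(n1+1)/2, R2 - n2(n2+1)/2)

is computed from the rank sums R1, R2 of the n1 V1-trials and n2
V2-trials. The combined statistic

    P = sum_j U_j / sum_j n1_j * n2_j

lies in [0, 1/2]; P = 0 means complete separation of spike counts by the
tested variable in every stratum, P near 1/2 means no difference.

Significance comes from a block-restricted permutation null: trial labels
of the tested variable are shuffled only within cells defined by the block
identity crossed with the held-fixed variables. Because the block prior
(stimulus side probability 20/80 or 80/20) drifts over the session, an
unrestricted shuffle would mistake any slow rate drift for selectivity;
restricting the shuffle to blocks removes this serial dependence. The
p-value is the fraction of permutations whose combined statistic is at
least as extreme (as small) as the observed one, and neurons with
p < 0.05 are labelled selective.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .spikes import SpikeTrain

__all__ = [
    "TrialTable",
    "SelectivityResults",
    "SelectivityModel",
    "TASK_VARIABLES",
    "DEFAULT_WINDOWS",
    "count_spikes_in_window",
    "stratify_trials",
    "choose_conditioning",
    "combined_u_statistic",
    "permutation_test",
]

TASK_VARIABLES = ("stimulus", "choice", "reward")

#: Event-aligned spike-count windows per variable, in seconds. The reward
#: window follows the feedback-aligned convention; the movement-aligned
#: [0, 150] ms variant can be passed explicitly.
DEFAULT_WINDOWS = {
    "stimulus": ("stimulus_onset", (0.0, 0.100)),
    "choice": ("movement_onset", (-0.100, 0.0)),
    "reward": ("feedback_onset", (0.0, 0.200)),
}

_VARIABLE_COLUMNS = {
    "stimulus": "stimulus_side",
    "choice": "choice",
    "reward": "reward",
}


@dataclass
class TrialTable:
    """Per-trial task variables and event times, backed by a DataFrame.

    Required columns: ``stimulus_side`` (left/right), ``contrast`` (%),
    ``choice`` (left/right), ``reward`` (bool), ``block_id`` (nondecreasing
    integer), and the event-time columns ``stimulus_onset``,
    ``movement_onset``, ``feedback_onset`` in seconds.
    """

    df: pd.DataFrame = field(repr=False)

    REQUIRED = ("stimulus_side", "contrast", "choice", "reward", "block_id",
                "stimulus_onset", "movement_onset", "feedback_onset")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise ValueError(f"trial table missing columns: {missing}")
        blocks = np.asarray(self.df["block_id"])
        if np.any(np.diff(blocks) < 0):
            raise ValueError("block_id must be nondecreasing")

    @property
    def n_trials(self) -> int:
        return len(self.df)

    def variable_labels(self, variable: str) -> np.ndarray:
        """Boolean labels for the V1 value of a task variable."""
        col = _VARIABLE_COLUMNS[variable]
        vals = np.asarray(self.df[col])
        if vals.dtype == bool:
            return vals
        uniq = np.unique(vals)
        if uniq.size > 2:
            raise ValueError(f"{variable} is not binary: {uniq}")
        return vals == uniq[0]


def count_spikes_in_window(train: SpikeTrain, events, window) -> tuple:
    """Spike counts in ``[event + a, event + b)`` per trial.

    Returns ``(counts, valid)`` where ``valid`` marks trials with a finite
    event time; invalid trials get count 0 and are meant to be dropped.
    """
    a, b = window
    if not a < b:
        raise ValueError("window must satisfy a < b")
    events = np.asarray(events, dtype=float)
    valid = np.isfinite(events)
    counts = np.zeros(events.size, dtype=np.int64)
    ev = events[valid]
    lo = np.searchsorted(train.spike_times, ev + a, side="left")
    hi = np.searchsorted(train.spike_times, ev + b, side="left")
    counts[valid] = hi - lo
    return counts, valid


def stratify_trials(table: TrialTable, variable: str,
                    held=None) -> np.ndarray:
    """Integer stratum codes from the held-fixed task variables.

    By default the two other variables of (stimulus, choice, reward) are
    held fixed; contrast is deliberately not a conditioning variable. Pass
    ``held`` to condition on a subset (empty = single stratum).
    """
    if variable not in TASK_VARIABLES:
        raise ValueError(f"unknown variable: {variable}")
    if held is None:
        held = [v for v in TASK_VARIABLES if v != variable]
    if not held:
        return np.zeros(table.n_trials, dtype=np.int64)
    cols = [pd.factorize(np.asarray(table.df[_VARIABLE_COLUMNS[v]]))[0]
            for v in held]
    return _combine_codes(cols)


def _usable_weight(labels_v1, strata) -> float:
    """Sum of n1j * n2j over strata containing both label values."""
    total = 0.0
    for s in np.unique(strata):
        z = labels_v1[strata == s]
        n1 = int(z.sum())
        n2 = z.size - n1
        if n1 and n2:
            total += n1 * n2
    return total


def choose_conditioning(table: TrialTable, variable: str) -> tuple:
    """Largest usable conditioning set for the tested variable.

    When reward is exactly determined by stimulus and choice, each task
    variable is a function of the other two, and conditioning on both
    leaves no stratum containing both values of the tested variable. In
    that case fall back to the single held variable whose strata carry
    the largest sum of n1j*n2j, then to no conditioning at all. Returns
    ``(held_variables, strata_codes)``.
    """
    z = table.variable_labels(variable)
    others = [v for v in TASK_VARIABLES if v != variable]
    # full conditioning first
    strata = stratify_trials(table, variable, held=others)
    if _usable_weight(z, strata) > 0:
        return others, strata
    # then the more informative single-variable conditioning
    best = None
    for v in others:
        strata = stratify_trials(table, variable, held=[v])
        w = _usable_weight(z, strata)
        if w > 0 and (best is None or w > best[0]):
            best = (w, [v], strata)
    if best is not None:
        return best[1], best[2]
    # finally no conditioning
    strata = stratify_trials(table, variable, held=[])
    if _usable_weight(z, strata) > 0:
        return [], strata
    raise ValueError("no conditioning set yields a usable stratum")


def _combine_codes(codes) -> np.ndarray:
    arr = np.asarray(codes)
    n_levels = arr.max(axis=1) + 1
    combined = arr[0].copy()
    for k in range(1, arr.shape[0]):
        combined = combined * n_levels[k] + arr[k]
    # relabel to consecutive 0..S-1
    _, out = np.unique(combined, return_inverse=True)
    return out


def combined_u_statistic(counts, labels_v1, strata) -> tuple:
    """Condition-combined Mann-Whitney statistic P and per-stratum detail.

    Ranks use the average-rank convention for ties, computed within each
    stratum. Strata in which either group is empty are excluded from both
    sums. Returns ``(P, detail)`` with a per-stratum record of U_j, n1_j,
    n2_j.
    """
    counts = np.asarray(counts, dtype=float)
    labels_v1 = np.asarray(labels_v1, dtype=bool)
    strata = np.asarray(strata)
    detail = []
    num = 0.0
    den = 0.0
    for s in np.unique(strata):
        idx = strata == s
        z = labels_v1[idx]
        n1 = int(z.sum())
        n2 = int(idx.sum()) - n1
        if n1 == 0 or n2 == 0:
            continue
        ranks = rankdata(counts[idx])
        r1 = float(ranks[z].sum())
        r2 = float(ranks[~z].sum())
        u = min(r1 - n1 * (n1 + 1) / 2.0, r2 - n2 * (n2 + 1) / 2.0)
        detail.append({"stratum": int(s), "U": u, "n1": n1, "n2": n2})
        num += u
        den += n1 * n2
    if den == 0:
        raise ValueError("no stratum with trials in both groups")
    return num / den, detail


@dataclass(frozen=True)
class SelectivityResults:
    """Selectivity of one unit to one task variable."""

    unit_id: object
    variable: str
    p_stat: float
    perm_p: float
    n_perm: int
    u_per_stratum: list
    n_dropped_trials: int
    conditioned_on: tuple = ()

    @property
    def selective(self) -> bool:
        return self.perm_p < 0.05

    def summary(self) -> str:
        return "\n".join([
            "Condition-combined Mann-Whitney selectivity test",
            "=" * 48,
            f"unit:            {self.unit_id}",
            f"variable:        {self.variable}",
            f"combined P:      {self.p_stat:.4f}",
            f"permutation p:   {self.perm_p:.4f}  ({self.n_perm} permutations)",
            f"selective:       {self.selective}",
            f"strata used:     {len(self.u_per_stratum)}",
            f"trials dropped:  {self.n_dropped_trials}",
        ])


class SelectivityModel:
    """Selectivity test of one spike train against one task variable.

    Parameters
    ----------
    train : the unit's spike train over the task period.
    table : trial table with task variables, block ids and event times.
    variable : one of "stimulus", "choice", "reward".
    window : optional ``(event_column, (a, b))`` override of the default
        event-aligned count window.
    """

    def __init__(self, train: SpikeTrain, table: TrialTable, variable: str,
                 window=None):
        if variable not in TASK_VARIABLES:
            raise ValueError(f"unknown variable: {variable}")
        self.train = train
        self.table = table
        self.variable = variable
        event_col, win = window if window is not None \
            else DEFAULT_WINDOWS[variable]
        counts, valid = count_spikes_in_window(
            train, table.df[event_col], win)
        self._counts = counts[valid]
        self._valid = valid
        self.n_dropped = int((~valid).sum())
        sub = table.df.loc[valid].reset_index(drop=True)
        self._table = TrialTable(sub)

    def fit(self, n_perm: int = 3000, seed=None,
            strict: bool = False) -> SelectivityResults:
        """Observed combined statistic and block-restricted permutation p."""
        return permutation_test(self._counts, self._table, self.variable,
                                n_perm=n_perm, seed=seed, strict=strict,
                                unit_id=self.train.unit_id,
                                n_dropped=self.n_dropped)


def permutation_test(counts, table: TrialTable, variable: str,
                     n_perm: int = 3000, seed=None, strict: bool = False,
                     unit_id=None, n_dropped: int = 0) -> SelectivityResults:
    """Block-restricted permutation test of the combined U statistic.

    Labels of the tested variable are shuffled within cells defined by
    (block x held-fixed variables); each block's label counts are thereby
    preserved exactly. The p-value is the fraction of permutations whose
    combined statistic is <= the observed one (``strict=True`` uses <),
    with no add-one smoothing.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    counts = np.asarray(counts, dtype=float)
    z = table.variable_labels(variable)
    held, strata = choose_conditioning(table, variable)
    p_obs, detail = combined_u_statistic(counts, z, strata)

    blocks = np.asarray(table.df["block_id"])
    cells = _combine_codes([pd.factorize(blocks)[0], strata])

    rng = np.random.default_rng(seed)
    Z = np.tile(z, (n_perm, 1))
    for c in np.unique(cells):
        idx = np.flatnonzero(cells == c)
        if idx.size > 1:
            Z[:, idx] = rng.permuted(Z[:, idx], axis=1)

    # Precompute per-stratum ranks; labels change across permutations but
    # counts (hence ranks) and per-stratum group sizes do not.
    num = np.zeros(n_perm)
    den = 0.0
    for rec in detail:
        s = rec["stratum"]
        idx = np.flatnonzero(strata == s)
        ranks = rankdata(counts[idx])
        n1, n2 = rec["n1"], rec["n2"]
        r1 = Z[:, idx].astype(float) @ ranks
        total = ranks.sum()
        u1 = r1 - n1 * (n1 + 1) / 2.0
        u2 = (total - r1) - n2 * (n2 + 1) / 2.0
        num += np.minimum(u1, u2)
        den += n1 * n2
    p_perm = num / den
    if strict:
        p_val = float(np.mean(p_perm < p_obs))
    else:
        p_val = float(np.mean(p_perm <= p_obs))
    return SelectivityResults(unit_id=unit_id, variable=variable,
                              p_stat=float(p_obs), perm_p=p_val,
                              n_perm=n_perm, u_per_stratum=detail,
                              n_dropped_trials=n_dropped,
                              conditioned_on=tuple(held))
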