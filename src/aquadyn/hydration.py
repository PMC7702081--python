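"""Cooperative hydration model: W_abc subpopulations, per-subpopulation
reorientation times, retardation factors, and the hydration number h.

Each water O_aH_bH_c is labelled by the shell state of its oxygen with
respect to the nearest cation (a) and of each hydrogen with respect to the
nearest anion (b, c), with states 1 (first shell), 2 (second shell) and B
(beyond).  The two hydrogens are exchangeable, so (b, c) is unordered:
3 x 6 = 18 labels.  Three of them (W_11B, W_21B, W_B1B) would require one
hydrogen in the anion's first shell while the other is beyond the second
shell, i.e. a dissociated O-H bond, and are flagged inadmissible.

For each populated subpopulation the dipole correlation C1(t) is computed by
origin membership (a water is attributed to the subpopulation it occupies at
the time origin and then tracked across the window), fit bi-exponentially,
and expressed as a retardation factor f_i = tau_i / tau_bulk.  Subpopulations
whose f falls outside the Empirical-Rule (68-95-99.7) band around bulk-like
behaviour are "slow"; the hydration number h is the number of slow waters
per dissolved salt unit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .traj_io import Trajectory, WaterTopology, minimum_image_distance
from .structure import ShellBoundaries
from .dynamics import correlate, dipole_series, fit_biexponential

__all__ = [
    "SubpopulationLabel",
    "HydrationResult",
    "enumerate_labels",
    "label_waters",
    "label_trajectory",
    "subpopulation_taus",
    "bulk_reference_tau",
    "retardation_factors",
    "classify_empirical_rule",
    "empirical_rule_iterate",
    "hydration_number",
]

_STATE_ORDER = {"1": 0, "2": 1, "B": 2}


class SubpopulationLabel(NamedTuple):
    """Canonical W_abc label; b <= c under the order 1 < 2 < B."""

    a: str
    b: str
    c: str

    @property
    def name(self) -> str:
        return f"W_{self.a}{self.b}{self.c}"

    @property
    def admissible(self) -> bool:
        # exactly one H in the anion first shell with the other beyond the
        # second shell would mean a dissociated O-H bond
        return not (self.b == "1" and self.c == "B")

    @classmethod
    def make(cls, a: str, b: str, c: str) -> "SubpopulationLabel":
        if sorted((b, c), key=_STATE_ORDER.get) != [b, c]:
            b, c = c, b
        return cls(a, b, c)


def enumerate_labels() -> list[SubpopulationLabel]:
    """All 18 canonical labels (15 admissible) in deterministic order."""
    states = ("1", "2", "B")
    out = []
    for a in states:
        for i, b in enumerate(states):
            for c in states[i:]:
                out.append(SubpopulationLabel(a, b, c))
    return out


LABELS = enumerate_labels()
LABEL_INDEX = {lab.name: i for i, lab in enumerate(LABELS)}


def _shell_state(d: np.ndarray, shells: ShellBoundaries) -> np.ndarray:
    """Map distances to shell states with half-open intervals
    [0, r_min1), [r_min1, r_min2), [r_min2, inf)."""
    state = np.full(d.shape, 2, dtype=int)  # B
    state[d < shells.r_min2] = 1
    state[d < shells.r_min1] = 0
    return state


def label_waters(
    positions: np.ndarray,
    topology: WaterTopology,
    cell: np.ndarray,
    cation: str,
    anion: str,
    cation_shells: ShellBoundaries,
    anion_shells: ShellBoundaries,
) -> np.ndarray:
    """Per-water label indices (into :data:`LABELS`) for one frame.

    a compares each O with the nearest cation against the cation-O shell
    boundaries; b and c compare each H with the nearest anion against the
    anion-H boundaries.  With no cations (or anions) present the respective
    states are B.
    """
    mols = topology.molecules
    n = mols.shape[0]
    states = "12B"

    cat_idx = topology.ion_indices.get(cation, np.empty(0, dtype=int))
    an_idx = topology.ion_indices.get(anion, np.empty(0, dtype=int))

    if cat_idx.size:
        d = minimum_image_distance(
            positions[mols[:, 0]][:, None, :], positions[cat_idx][None, :, :], cell
        ).min(axis=1)
        a_state = _shell_state(d, cation_shells)
    else:
        a_state = np.full(n, 2, dtype=int)

    if an_idx.size:
        h_atoms = mols[:, 1:].ravel()
        d = minimum_image_distance(
            positions[h_atoms][:, None, :], positions[an_idx][None, :, :], cell
        ).min(axis=1).reshape(n, 2)
        bc_state = _shell_state(d, anion_shells)
    else:
        bc_state = np.full((n, 2), 2, dtype=int)

    out = np.empty(n, dtype=int)
    for i in range(n):
        lab = SubpopulationLabel.make(
            states[a_state[i]], states[bc_state[i, 0]], states[bc_state[i, 1]]
        )
        out[i] = LABEL_INDEX[lab.name]
    return out


def label_trajectory(
    traj: Trajectory,
    topology: WaterTopology,
    cation: str,
    anion: str,
    cation_shells: ShellBoundaries,
    anion_shells: ShellBoundaries,
) -> np.ndarray:
    """(n_frames, n_waters) label-index array over the whole trajectory."""
    return np.stack(
        [
            label_waters(
                traj.positions[f], topology, traj.cell[f],
                cation, anion, cation_shells, anion_shells,
            )
            for f in range(traj.n_frames)
        ]
    )


def _origin_groups(n_origin_frames: int, n_blocks: int) -> list[slice]:
    edges = np.linspace(0, n_origin_frames, n_blocks + 1).astype(int)
    return [slice(edges[i], edges[i + 1]) for i in range(n_blocks)]


def subpopulation_taus(
    traj: Trajectory,
    topology: WaterTopology,
    labels: np.ndarray,
    window: float = 16.0,
    fit_start: float = 0.2,
    origin_stride: int | None = None,
    n_blocks: int = 4,
    target_origins: int = 1024,
) -> pd.DataFrame:
    """Per-subpopulation populations and reorientation times.

    Returns a DataFrame indexed by label name with columns
    ``population, pop_sigma, tau_ps, tau_sigma, n_origins, class`` (class is
    "empty" for never-populated labels, otherwise empty string until
    classification).  Population uncertainties come from ``n_blocks``
    non-overlapping frame blocks; tau uncertainties from refitting C1 with
    the time origins split into ``n_blocks`` consecutive groups.

    ``origin_stride=None`` derives the stride from the trajectory length to
    target about ``target_origins`` time origins.
    """
    labels = np.asarray(labels)
    n_frames, n_waters = labels.shape
    n_lags = int(round(window / traj.dt)) + 1
    avail = n_frames - n_lags + 1
    if avail < 1:
        raise ValueError("window longer than trajectory")
    if origin_stride is None:
        origin_stride = max(1, int(np.ceil(avail / target_origins)))

    mu = dipole_series(traj, topology)

    frame_blocks = _origin_groups(n_frames, n_blocks)
    origin_blocks = _origin_groups(avail, n_blocks)

    rows = []
    curves: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for li, lab in enumerate(LABELS):
        mask = labels == li
        pops = mask.sum(axis=1)
        population = float(pops.mean())
        block_means = [pops[b].mean() for b in frame_blocks if pops[b].size]
        pop_sigma = (
            float(np.std(block_means, ddof=1) / np.sqrt(len(block_means)))
            if len(block_means) > 1
            else 0.0
        )
        row = {
            "label": lab.name, "a": lab.a, "b": lab.b, "c": lab.c,
            "admissible": lab.admissible,
            "population": population, "pop_sigma": pop_sigma,
            "tau_ps": np.nan, "tau_sigma": np.nan, "n_origins": 0,
            "class": "empty",
        }
        origin_pops = mask[:avail]
        if lab.admissible and origin_pops.any():
            try:
                c1 = correlate(
                    mu, traj.dt, window, origin_stride=origin_stride,
                    kernel="dot", origin_selection=mask,
                )
                curves[lab.name] = (c1.lags.copy(), c1.values.copy())
                fit = fit_biexponential(c1, fit_start=fit_start)
                row["tau_ps"] = fit.tau_reor
                row["n_origins"] = int(c1.n_origins[0])
                row["class"] = ""
                block_taus = []
                for ob in origin_blocks:
                    sub = slice(ob.start, min(ob.stop - 1 + n_lags, n_frames))
                    if not mask[ob].any():
                        continue
                    try:
                        c1b = correlate(
                            mu[sub], traj.dt, window, origin_stride=origin_stride,
                            kernel="dot", origin_selection=mask[sub],
                        )
                        block_taus.append(fit_biexponential(c1b, fit_start).tau_reor)
                    except (ValueError, RuntimeError):
                        continue
                if len(block_taus) > 1:
                    row["tau_sigma"] = float(
                        np.std(block_taus, ddof=1) / np.sqrt(len(block_taus))
                    )
            except (ValueError, RuntimeError):
                pass  # stays empty
        rows.append(row)
    df = pd.DataFrame(rows).set_index("label")
    df.attrs["c1_curves"] = curves  # per-label C1(t), for export/plotting
    return df


def bulk_reference_tau(table: pd.DataFrame) -> float:
    """Population-weighted mean tau over the seed bulk-like set.

    The seed set contains the subpopulations expected a priori to behave
    bulk-like: oxygen not in the cation first shell (a != 1) and no hydrogen
    in the anion first shell.  Using a set (rather than W_BBB alone) matters
    at high concentration, where W_BBB can be empty.
    """
    seed = _seed_mask(table) & table["tau_ps"].notna()
    if not seed.any():
        seed = table["tau_ps"].notna() & (
            table["tau_ps"] == table.loc[table["tau_ps"].notna(), "tau_ps"].min()
        )
    w = table.loc[seed, "population"].to_numpy()
    tau = table.loc[seed, "tau_ps"].to_numpy()
    if w.sum() == 0:
        w = np.ones_like(w)
    return float(np.average(tau, weights=w))


def retardation_factors(table: pd.DataFrame, bulk_tau: float) -> pd.DataFrame:
    """Add retardation factors f_i = tau_i / tau_bulk (and propagated sigma)."""
    if bulk_tau <= 0:
        raise ValueError("bulk_tau must be positive")
    out = table.copy()
    out["f"] = out["tau_ps"] / bulk_tau
    out["f_sigma"] = out["tau_sigma"] / bulk_tau
    out.attrs["bulk_tau"] = bulk_tau
    return out


def _seed_mask(table: pd.DataFrame) -> pd.Series:
    return (
        (table["a"] != "1")
        & (table["b"] != "1")
        & (table["c"] != "1")
        & (table["population"] > 0)
    )


def empirical_rule_iterate(
    f: np.ndarray,
    pop: np.ndarray,
    seed: np.ndarray,
    f_sigma: np.ndarray | None = None,
    n_sigma: float = 3.0,
    sigma_mode: str = "combined",
    max_iter: int = 100,
) -> tuple[np.ndarray, float, float]:
    """Iterate the n-sigma bulk-like band to a fixed point.

    At each step the population-weighted mean and standard deviation of f
    over the current bulk-like set are computed and every entry is
    reclassified as bulk-like iff |f - mean| <= n_sigma * sigma.  sigma is
    the weighted spread of f ("spread"), the weighted rms of the per-entry
    block errors ("blocks"), or the two combined in quadrature
    ("combined", default).

    Returns (bulk mask, mean, sigma).
    """
    f = np.asarray(f, dtype=float)
    pop = np.asarray(pop, dtype=float)
    valid = np.isfinite(f)
    bulk = np.asarray(seed, dtype=bool) & valid
    if not bulk.any():
        # fall back to the smallest finite f as seed
        bulk = valid & (f == np.nanmin(f))
    if f_sigma is None:
        f_sigma = np.zeros_like(f)
    f_sigma = np.nan_to_num(np.asarray(f_sigma, dtype=float))

    mean = sigma = 0.0
    for _ in range(max_iter):
        w = pop[bulk]
        if w.sum() <= 0:
            w = np.ones(bulk.sum())
        mean = float(np.average(f[bulk], weights=w))
        spread = float(np.sqrt(np.average((f[bulk] - mean) ** 2, weights=w)))
        blocks = float(np.sqrt(np.average(f_sigma[bulk] ** 2, weights=w)))
        if sigma_mode == "spread":
            sigma = spread
        elif sigma_mode == "blocks":
            sigma = blocks
        elif sigma_mode == "combined":
            sigma = float(np.hypot(spread, blocks))
        else:
            raise ValueError("sigma_mode must be spread|blocks|combined")
        new_bulk = valid & (np.abs(f - mean) <= n_sigma * sigma)
        if not new_bulk.any():
            break  # degenerate band; keep the previous assignment
        if np.array_equal(new_bulk, bulk):
            bulk = new_bulk
            break
        bulk = new_bulk
    return bulk, mean, sigma


def classify_empirical_rule(
    table: pd.DataFrame,
    n_sigma: float = 3.0,
    sigma_mode: str = "combined",
) -> pd.DataFrame:
    """Classify populated subpopulations as bulk-like or slow.

    Seeds the bulk set with the labels expected bulk-like a priori (a != 1,
    no H in the anion first shell), then iterates the Empirical-Rule band to
    a fixed point.  Labels with no population keep class "empty".
    """
    populated = table["tau_ps"].notna() & (table["population"] > 0)
    if populated.sum() < 2:
        raise ValueError("need at least two populated subpopulations to classify")
    f = table["f"].to_numpy(dtype=float)
    f = np.where(populated.to_numpy(), f, np.nan)
    bulk, mean, sigma = empirical_rule_iterate(
        f,
        table["population"].to_numpy(dtype=float),
        _seed_mask(table).to_numpy() & populated.to_numpy(),
        f_sigma=table["f_sigma"].to_numpy(dtype=float) if "f_sigma" in table else None,
        n_sigma=n_sigma,
        sigma_mode=sigma_mode,
    )
    out = table.copy()
    cls = np.where(populated.to_numpy(), np.where(bulk, "bulk-like", "slow"), "empty")
    out["class"] = cls
    out.attrs["bulk_f_mean"] = mean
    out.attrs["bulk_f_sigma"] = sigma
    out.attrs["n_sigma"] = n_sigma
    return out


@dataclass
class HydrationResult:
    """Hydration number h and its first-shell / beyond decomposition
    (waters per dissolved salt unit)."""

    h: float
    slow_first_shell: float
    slow_beyond: float
    bulk_reference_tau: float
    block_errors: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "h": self.h,
            "slow_first_shell": self.slow_first_shell,
            "slow_beyond": self.slow_beyond,
            "bulk_reference_tau_ps": self.bulk_reference_tau,
            "block_errors": self.block_errors,
        }


def hydration_number(
    table: pd.DataFrame, n_salt_units: float, bulk_tau: float | None = None
) -> HydrationResult:
    """Hydration number h = slow waters per dissolved salt unit.

    Splits h into the contribution from the cation first shell (a = 1) and
    from beyond it.  The population block error of the slow set is
    propagated to h.
    """
    if n_salt_units <= 0:
        raise ValueError("n_salt_units must be positive")
    if "class" not in table:
        raise ValueError("table is not classified; run classify_empirical_rule first")
    slow = table["class"] == "slow"
    first = slow & (table["a"] == "1")
    beyond = slow & (table["a"] != "1")
    h_first = float(table.loc[first, "population"].sum()) / n_salt_units
    h_beyond = float(table.loc[beyond, "population"].sum()) / n_salt_units
    h_sigma = float(np.sqrt((table.loc[slow, "pop_sigma"] ** 2).sum())) / n_salt_units
    return HydrationResult(
        h=h_first + h_beyond,
        slow_first_shell=h_first,
        slow_beyond=h_beyond,
        bulk_reference_tau=float(
            bulk_tau if bulk_tau is not None else table.attrs.get("bulk_tau", np.nan)
        ),
        block_errors={"h_sigma": h_sigma},
    )
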