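"""Inter-limb coordination modes (ILCMs) and gait statistics for hands-knees crawling.

A crawling cycle runs from one left-palm (LP) touchdown to the next.  Within a
cycle the four limbs — left palm (LP), right palm (RP), left knee (LK), right
knee (RK) — touch down in a mode-specific order, either in pairs (trot/pace
style) or one at a time (sequence gaits).  The ipsilateral phase lag

    IPL = (b / a) * 100%

with ``a`` the cycle duration and ``b`` the LP-to-LK touchdown lag, summarises
the coordination: values near 0/100% indicate pace gait (ipsilateral pairing),
near 50% trot gait (diagonal pairing), and near 25%/75% no-limb-pairing
(sequence) gaits.  The duty factor of a limb's stance phase is
``stance / (stance + swing) * 100%``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LIMBS",
    "ILCMDefinition",
    "GaitTiming",
    "ILCM_CATALOG",
    "get_mode",
    "ideal_schedule",
    "compute_ipl",
    "duty_factor",
    "categorize_ipl",
    "catalog_to_json",
    "catalog_from_json",
]

LIMBS = ("LP", "RP", "LK", "RK")

#: ideal IPL values and the gait category they label
_IDEAL_IPL_CATEGORY = {0.0: "pace", 25.0: "no-limb-pairing", 50.0: "trot",
                       75.0: "no-limb-pairing", 100.0: "pace"}


class MidpointIPLWarning(UserWarning):
    """An IPL value sat exactly between two ideal gait values."""


@dataclass(frozen=True)
class ILCMDefinition:
    """One inter-limb coordination mode.

    Parameters
    ----------
    mode_id:
        ``"M1"`` … ``"M8"``.
    landing_order:
        Ordered event groups; each group is the set of limbs touching down
        simultaneously.  The first group always contains LP, which initiates
        the cycle.
    """

    mode_id: str
    landing_order: tuple[frozenset[str], ...]
    ideal_phase: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        limbs = [l for grp in self.landing_order for l in grp]
        if sorted(limbs) != sorted(LIMBS):
            raise ValueError(
                f"{self.mode_id}: each limb must appear in exactly one event group"
            )
        if "LP" not in self.landing_order[0]:
            raise ValueError(f"{self.mode_id}: the first event group must contain LP")
        if not self.ideal_phase:
            # uniform spacing: halves for two groups, quarters for four
            n = len(self.landing_order)
            phases = {}
            for i, grp in enumerate(self.landing_order):
                for limb in grp:
                    phases[limb] = i / n
            object.__setattr__(self, "ideal_phase", phases)
        if abs(self.ideal_phase["LP"]) > 1e-12:
            raise ValueError(f"{self.mode_id}: LP phase must be 0")

    @property
    def ideal_ipl(self) -> float:
        """Ideal IPL in percent: the LK touchdown phase x 100 (0 ≡ 100)."""
        return self.ideal_phase["LK"] * 100.0


def _mode(mode_id: str, *groups: str) -> ILCMDefinition:
    return ILCMDefinition(mode_id, tuple(frozenset(g.split("+")) for g in groups))


#: the eight designed coordination modes, keyed by mode id
ILCM_CATALOG: dict[str, ILCMDefinition] = {
    m.mode_id: m
    for m in (
        _mode("M1", "LP+LK", "RP+RK"),        # pace, ideal IPL 0 (≡100)
        _mode("M2", "LP+RK", "RP+LK"),        # trot, 50
        _mode("M3", "LP", "RP", "LK", "RK"),  # 50
        _mode("M4", "LP", "RP", "RK", "LK"),  # 75
        _mode("M5", "LP", "LK", "RP", "RK"),  # 25
        _mode("M6", "LP", "LK", "RK", "RP"),  # 25
        _mode("M7", "LP", "RK", "RP", "LK"),  # 75
        _mode("M8", "LP", "RK", "LK", "RP"),  # 50
    )
}


def get_mode(mode_id: str) -> ILCMDefinition:
    try:
        return ILCM_CATALOG[mode_id]
    except KeyError:
        raise KeyError(f"unknown ILCM id {mode_id!r}; expected one of M1..M8") from None


@dataclass
class GaitTiming:
    """Per-limb touchdown/liftoff times over a trial.

    ``events[limb]`` is an (n, 2) float array of ``(touchdown_s, liftoff_s)``
    pairs, strictly increasing, with touchdown < liftoff within each pair.
    """

    events: dict[str, np.ndarray]
    cycle_duration_s: float | None = None
    stance_fraction: dict[str, float] | None = None

    def __post_init__(self) -> None:
        for limb, ev in self.events.items():
            ev = np.asarray(ev, dtype=float).reshape(-1, 2)
            self.events[limb] = ev
            if ev.size and np.any(ev[:, 1] <= ev[:, 0]):
                raise ValueError(f"{limb}: touchdown must precede liftoff")
            if ev.shape[0] > 1 and np.any(np.diff(ev[:, 0]) <= 0):
                raise ValueError(f"{limb}: events must be strictly increasing")

    def touchdowns(self, limb: str) -> np.ndarray:
        return self.events[limb][:, 0]

    @property
    def n_cycles(self) -> int:
        """Number of complete LP-to-LP cycles."""
        return max(len(self.events["LP"]) - 1, 0)

    @property
    def span_s(self) -> float:
        return float(max(ev[-1, 1] for ev in self.events.values() if ev.size))


def ideal_schedule(
    mode: ILCMDefinition | str,
    cycle_duration: float,
    stance_fraction: float = 0.7,
    n_cycles: int = 1,
) -> GaitTiming:
    """Noise-free limb timing for ``n_cycles`` cycles of one coordination mode.

    Limb ``l`` touches down in cycle ``k`` at ``(k + phase[l]) * cycle_duration``
    and lifts off ``stance_fraction * cycle_duration`` later.  An extra LP
    touchdown closes the final cycle so that the schedule contains ``n_cycles``
    complete LP-to-LP intervals.
    """
    if isinstance(mode, str):
        mode = get_mode(mode)
    if cycle_duration <= 0:
        raise ValueError("cycle_duration must be positive")
    if not 0 < stance_fraction < 1:
        raise ValueError("stance_fraction must lie in (0, 1)")
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    stance = stance_fraction * cycle_duration
    events: dict[str, np.ndarray] = {}
    for limb in LIMBS:
        n = n_cycles + 1 if limb == "LP" else n_cycles
        td = (np.arange(n) + mode.ideal_phase[limb]) * cycle_duration
        events[limb] = np.column_stack([td, td + stance])
    return GaitTiming(events, cycle_duration_s=cycle_duration,
                      stance_fraction={l: stance_fraction for l in LIMBS})


def compute_ipl(lp_touchdowns, lk_touchdowns) -> np.ndarray:
    """Per-cycle ipsilateral phase lag, in percent.

    For each cycle — the half-open interval between consecutive LP
    touchdowns — exactly one LK touchdown must occur; the IPL of that cycle is
    ``(b / a) * 100`` with ``a`` the LP-to-LP interval and ``b`` the LP-to-LK
    lag.  Values lie in [0, 100).
    """
    lp = np.asarray(lp_touchdowns, dtype=float)
    lk = np.asarray(lk_touchdowns, dtype=float)
    if lp.ndim != 1 or lp.size < 2:
        raise ValueError("need at least two LP touchdowns (one complete cycle)")
    if np.any(np.diff(lp) <= 0) or (lk.size > 1 and np.any(np.diff(lk) <= 0)):
        raise ValueError("event times must be strictly increasing")
    out = np.empty(lp.size - 1)
    for i in range(lp.size - 1):
        inside = lk[(lk >= lp[i]) & (lk < lp[i + 1])]
        if inside.size != 1:
            raise ValueError(
                f"cycle {i}: expected exactly one LK touchdown, found {inside.size}"
            )
        out[i] = (inside[0] - lp[i]) / (lp[i + 1] - lp[i]) * 100.0
    return out


def duty_factor(stance_duration, swing_duration):
    """Duty factor of the stance phase, ``stance/(stance+swing) * 100`` percent."""
    s = np.asarray(stance_duration, dtype=float)
    w = np.asarray(swing_duration, dtype=float)
    if np.any(s < 0) or np.any(w < 0):
        raise ValueError("durations must be nonnegative")
    total = s + w
    if np.any(total == 0):
        raise ValueError("stance and swing cannot both be zero")
    out = s / total * 100.0
    return float(out) if out.ndim == 0 else out


def circular_ipl_distance(ipl: float, ideal: float) -> float:
    """Distance between two IPL values on the 0–100 circle (100 ≡ 0)."""
    d = abs(ipl - ideal) % 100.0
    return min(d, 100.0 - d)


def categorize_ipl(ipl: float) -> str:
    """Assign an IPL value to {pace, trot, no-limb-pairing}.

    Nearest-ideal assignment among {0, 25, 50, 75, 100} with 100 ≡ 0; exact
    midpoints (12.5, 37.5, 62.5, 87.5) break toward the larger ideal and emit a
    :class:`MidpointIPLWarning`.
    """
    if not 0 <= ipl <= 100:
        raise ValueError("IPL must lie in [0, 100]")
    ipl = ipl % 100.0
    ideals = sorted(_IDEAL_IPL_CATEGORY)
    dists = [circular_ipl_distance(ipl, v) for v in ideals]
    best = min(dists)
    winners = [v for v, d in zip(ideals, dists) if abs(d - best) < 1e-12]
    # 0 and 100 are the same point on the wrap; a joint win is not a tie
    if set(winners) == {0.0, 100.0}:
        winners = [100.0] if ipl > 50.0 else [0.0]
    if len(winners) > 1:
        warnings.warn(
            f"IPL {ipl} is equidistant from ideals {winners}; "
            "breaking toward the larger",
            MidpointIPLWarning,
            stacklevel=2,
        )
    return _IDEAL_IPL_CATEGORY[max(winners)]


def catalog_to_json(catalog: dict[str, ILCMDefinition] | None = None) -> str:
    """Serialize the ILCM catalog as a JSON document."""
    catalog = catalog if catalog is not None else ILCM_CATALOG
    doc = [
        {
            "mode_id": m.mode_id,
            "landing_order": [sorted(g) for g in m.landing_order],
            "ideal_phase": m.ideal_phase,
        }
        for m in catalog.values()
    ]
    return json.dumps(doc, indent=2)


def catalog_from_json(text: str) -> dict[str, ILCMDefinition]:
    out = {}
    for entry in json.loads(text):
        mode = ILCMDefinition(
            entry["mode_id"],
            tuple(frozenset(g) for g in entry["landing_order"]),
            dict(entry["ideal_phase"]),
        )
        out[mode.mode_id] = mode
    return out
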