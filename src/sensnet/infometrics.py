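"""Module entropy, structural-alert information gain, and molecular-weight
threshold optimization.

For a module M with sensitizer fraction p, the (base-2) Shannon entropy

    H(M) = -p log2 p - (1-p) log2 (1-p)

lies in [0, 1]: 0 for a pure module, 1 for an even mixture. The information
gain of a boolean attribute is the parent entropy minus the
prevalence-weighted entropies of the attribute-positive and
attribute-negative children:

    I(M | a) = H_p - p(a) H_pa - p(!a) H_pn

Normalized gain rescales by the parent entropy (x100), so 100 means the
attribute perfectly separates sensitizers from non-sensitizers and 0 means
it leaves the mixture untouched; it is undefined (n/a) for pure modules.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .io_model import ChemicalRecord, NON_SENSITIZER, SENSITIZER
from .network import ModulePartition, UNDEFINED_MODULE

logger = logging.getLogger(__name__)

_GAIN_TOL = 1e-9


def entropy(n_sens: int, n_non: int) -> float:
    """Base-2 Shannon entropy of a module's label mixture (0 log 0 := 0)."""
    if n_sens < 0 or n_non < 0:
        raise ValueError("counts must be non-negative")
    total = n_sens + n_non
    if total == 0:
        raise ValueError("entropy undefined for an empty module")
    h = 0.0
    for n in (n_sens, n_non):
        if n:
            p = n / total
            h -= p * math.log2(p)
    return h


def _as_bool_labels(labels: Sequence) -> list[bool]:
    out = []
    for lab in labels:
        if lab is True or lab == SENSITIZER:
            out.append(True)
        elif lab is False or lab == NON_SENSITIZER:
            out.append(False)
        else:
            raise ValueError(f"label {lab!r} is not sensitizer/non-sensitizer")
    return out


def information_gain(labels: Sequence, feature: Sequence[bool]) -> float:
    """Information gain of a boolean feature over binary labels.

    ``labels`` may be booleans (True = sensitizer) or the label vocabulary
    strings; unknown labels must be excluded upstream. Children with zero
    members contribute 0.
    """
    y = _as_bool_labels(labels)
    if len(y) != len(feature):
        raise ValueError("labels and feature must be the same length")
    if not y:
        raise ValueError("need at least one labeled chemical")
    n = len(y)
    parent = entropy(sum(y), n - sum(y))

    def child(members: list[bool]) -> float:
        if not members:
            return 0.0
        return len(members) / n * entropy(sum(members), len(members) - sum(members))

    pos = [lab for lab, f in zip(y, feature) if f]
    neg = [lab for lab, f in zip(y, feature) if not f]
    gain = parent - child(pos) - child(neg)
    return max(gain, 0.0)  # clip away negative float dust


def normalized_gain(gain: float, parent_entropy: float) -> float | None:
    """100 x gain / parent entropy; None (n/a) when the parent is pure."""
    if gain > parent_entropy + _GAIN_TOL:
        raise ValueError(f"gain {gain} exceeds parent entropy {parent_entropy}")
    if parent_entropy == 0.0:
        return None
    return 100.0 * min(gain, parent_entropy) / parent_entropy


class MwSplit(NamedTuple):
    """Best molecular-weight split of a labeled set: the threshold t of the
    test MW < t, its raw information gain, and the entropy-normalized gain
    (None when the parent is pure)."""

    threshold: float | None
    gain: float
    norm_gain: float | None


def best_mw_threshold(mws: Sequence[float], labels: Sequence) -> MwSplit:
    """Molecular-weight threshold maximizing information gain.

    Candidate thresholds are the midpoints between consecutive distinct
    sorted MWs; the full candidate set is scanned and ties break toward the
    smallest threshold. With all labels identical the gain is 0 and the
    threshold is reported as n/a (None) with a warning.
    """
    y = _as_bool_labels(labels)
    if len(mws) != len(y):
        raise ValueError("mws and labels must be the same length")
    if len(y) < 1:
        raise ValueError("need at least one labeled chemical")
    parent = entropy(sum(y), len(y) - sum(y))
    if parent == 0.0:
        logger.warning("all labels identical: no MW threshold is informative")
        return MwSplit(None, 0.0, None)

    distinct = sorted(set(mws))
    candidates = [(a + b) / 2 for a, b in zip(distinct, distinct[1:])]
    if not candidates:
        logger.warning("all MWs identical: no MW threshold is informative")
        return MwSplit(None, 0.0, 0.0)

    best_t, best_gain = None, -1.0
    for t in candidates:
        gain = information_gain(y, [mw < t for mw in mws])
        if gain > best_gain + _GAIN_TOL:
            best_t, best_gain = t, gain
    return MwSplit(best_t, best_gain, normalized_gain(best_gain, parent))


# ---------------------------------------------------------------------------
# per-module statistics table

_ALERT_COLUMNS = (("SN2", "sn2"), ("MA", "ma"), ("SB", "sb"),
                  ("AA", "aa"), ("SNAr", "snar"), ("RD", "rd"))


@dataclass
class ModuleStats:
    """Entropy and attribute information for one module (labeled members only)."""

    module: str
    count: int            # all members, labeled or not
    n_sens: int
    n_non: int
    entropy: float | None
    alert_gains: dict[str, float | None] = field(default_factory=dict)
    mw_threshold: float | None = None
    mw_gain: float | None = None


def _stats_for(module: str, members: list[ChemicalRecord]) -> ModuleStats:
    labeled = [c for c in members if c.label in (SENSITIZER, NON_SENSITIZER)]
    n_sens = sum(1 for c in labeled if c.label == SENSITIZER)
    n_non = len(labeled) - n_sens
    if not labeled:
        return ModuleStats(module, len(members), 0, 0, None,
                           {col: None for col, _ in _ALERT_COLUMNS})
    h = entropy(n_sens, n_non)
    labels = [c.label for c in labeled]
    gains: dict[str, float | None] = {}
    for col, fname in _ALERT_COLUMNS:
        feature = [c.alert_flags.get(fname) for c in labeled]
        gains[col] = normalized_gain(information_gain(labels, feature), h) \
            if h > 0 else None
    if h > 0 and len({c.mw for c in labeled}) >= 2:
        split = best_mw_threshold([c.mw for c in labeled], labels)
        mw_threshold, mw_gain = split.threshold, split.norm_gain
    else:
        mw_threshold, mw_gain = None, None
    return ModuleStats(module, len(members), n_sens, n_non, h, gains,
                       mw_threshold, mw_gain)


def module_stats_table(partition: ModulePartition,
                       chems: Sequence[ChemicalRecord]) -> list[ModuleStats]:
    """Per-module entropy, alert information gains and best MW threshold.

    Returns one :class:`ModuleStats` per module plus ALL and Undefined rows.
    Unknown-label chemicals are excluded from entropy/gain computations, so
    the labeled counts may be smaller than the module size (both are kept).
    Requires mw and alert flags on every labeled chemical.
    """
    by_id = {c.id: c for c in chems}
    rows = [_stats_for("ALL", list(chems))]
    undef = [by_id[cid] for cid, m in partition.assignment.items()
             if m == UNDEFINED_MODULE and cid in by_id]
    rows.append(_stats_for("Undefined", undef))
    for mid in partition.module_ids:
        members = [by_id[cid] for cid in partition.members(mid) if cid in by_id]
        rows.append(_stats_for(str(mid), members))
    return rows


def stats_to_frame(stats: Sequence[ModuleStats]) -> pd.DataFrame:
    """Render ModuleStats as a table (Entropy, per-alert normalized gains,
    MW gain and MW Threshold columns; n/a as NaN)."""
    records = []
    for s in stats:
        rec = {"Module": s.module, "Count": s.count, "Labeled": s.n_sens + s.n_non,
               "Entropy": np.nan if s.entropy is None else s.entropy}
        for col, _ in _ALERT_COLUMNS:
            val = s.alert_gains.get(col)
            rec[col] = np.nan if val is None else val
        rec["MW"] = np.nan if s.mw_gain is None else s.mw_gain
        rec["MW Threshold"] = np.nan if s.mw_threshold is None else s.mw_threshold
        records.append(rec)
    return pd.DataFrame.from_records(records).set_index("Module")
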