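"""Intra- and inter-assay classification agreement and animal-use estimates.

Chemicals tested repeatedly — within one assay (e.g. two LLNA studies) or
across assays (GPMT vs LLNA) — bound how reproducible any replacement
method can look in direct comparison. The agreement matrix reports, for
each pair of study types, the percentage of qualifying chemicals whose
per-type classification calls agree, together with the number of chemicals
contributing to each cell.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

from .io_model import (OUTCOME_INCONCLUSIVE, OUTCOME_NON, OUTCOME_SENS,
                       StudyRecord)

AGREEMENT_TYPES = ("Buehler", "GPMT", "PatchTest", "LLNA")

TIE = "tie"


def per_type_call(studies: Sequence[StudyRecord]) -> str:
    """Majority classification call from one chemical's studies of one type.

    Conclusive outcomes only; an even split is a tie. No conclusive study
    leaves the call undefined (error — skip the chemical upstream).
    """
    n_sens = sum(1 for s in studies if s.outcome == OUTCOME_SENS)
    n_non = sum(1 for s in studies if s.outcome == OUTCOME_NON)
    if n_sens + n_non == 0:
        raise ValueError("no conclusive studies: call undefined")
    if n_sens > n_non:
        return "sens"
    if n_non > n_sens:
        return "non"
    return TIE


def agreement_matrix(studies: Sequence[StudyRecord],
                     types: Sequence[str] = AGREEMENT_TYPES
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise percent agreement between study types.

    Returns (percent, counts) DataFrames indexed by study type. The
    diagonal (A, A) covers chemicals with at least two conclusive studies
    of type A and reports the percentage whose outcomes are all concordant.
    An off-diagonal cell (A, B) covers chemicals with at least one
    conclusive study of each type and a non-tie majority call for both, and
    reports the percentage whose two calls match. Cells with no qualifying
    chemical are n/a (NaN) with count 0. The matrix is symmetric and
    independent of study input order.
    """
    by_chem_type: dict[tuple[str, str], list[StudyRecord]] = {}
    for s in studies:
        if s.study_type in types and s.outcome != OUTCOME_INCONCLUSIVE:
            by_chem_type.setdefault((s.chemical_id, s.study_type), []).append(s)

    chem_ids = sorted({cid for cid, _ in by_chem_type})
    pct = pd.DataFrame(index=list(types), columns=list(types), dtype=float)
    cnt = pd.DataFrame(0, index=list(types), columns=list(types), dtype=int)

    for i, type_a in enumerate(types):
        for type_b in types[i:]:
            agree = total = 0
            for cid in chem_ids:
                if type_a == type_b:
                    group = by_chem_type.get((cid, type_a))
                    if group is None or len(group) < 2:
                        continue
                    outcomes = {s.outcome for s in group}
                    total += 1
                    agree += len(outcomes) == 1
                else:
                    group_a = by_chem_type.get((cid, type_a))
                    group_b = by_chem_type.get((cid, type_b))
                    if not group_a or not group_b:
                        continue
                    call_a, call_b = per_type_call(group_a), per_type_call(group_b)
                    if TIE in (call_a, call_b):
                        continue
                    total += 1
                    agree += call_a == call_b
            value = 100.0 * agree / total if total else float("nan")
            pct.loc[type_a, type_b] = pct.loc[type_b, type_a] = value
            cnt.loc[type_a, type_b] = cnt.loc[type_b, type_a] = total
    return pct, cnt


def estimate_animal_use(studies: Sequence[StudyRecord],
                        per_type_animals: Mapping[str, float]) -> pd.Series:
    """Estimated animals used per year: sum over studies of the per-type
    average animal count. Every study type present must appear in the map.
    """
    totals: dict[int, float] = {}
    for s in studies:
        if s.study_type not in per_type_animals:
            raise ValueError(
                f"study type {s.study_type!r} missing from per_type_animals")
        totals[s.year] = totals.get(s.year, 0.0) + per_type_animals[s.study_type]
    return pd.Series(totals, dtype=float).sort_index()
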