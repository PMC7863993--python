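"""Relative conformer-energy agreement between a force field and QM.

Per-structure ddE values anchor both energy scales at the group's
lowest-QM-energy conformer; per-molecule mean signed deviation (MSD) is
computed over matched, non-reference conformers; fraction-within and
extrema summaries aggregate per force field.
"""

from __future__ import annotations

import logging
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FFBenchError
from .io_dataset import MoleculeGroup

__all__ = [
    "DEFAULT_PATHOLOGY_THRESHOLD",
    "DEFAULT_WITHIN_THRESHOLD",
    "dde",
    "energy_table",
    "msd",
    "msd_by_molecule",
    "fraction_within",
    "extrema_summary",
]

logger = logging.getLogger(__name__)

#: |ddE| (kcal/mol) beyond which a row is treated as pathological (e.g.
#: hydrogen-collapse geometries with absurd minimized energies).
DEFAULT_PATHOLOGY_THRESHOLD = 1.0e4

#: kcal/mol window for fraction-within summaries.
DEFAULT_WITHIN_THRESHOLD = 1.0

_TABLE_COLUMNS = [
    "key",
    "title",
    "conf_index",
    "ff_id",
    "qm_energy",
    "ff_energy",
    "de_qm",
    "de_ff",
    "dde",
    "is_reference",
    "pathological",
]


def dde(
    group: MoleculeGroup,
    ff_id: str,
    pathology_threshold: float = DEFAULT_PATHOLOGY_THRESHOLD,
) -> pd.DataFrame:
    """Per-conformer relative-energy rows for one group and force field.

    ddE_i = [FFenergy(i) - FFenergy(0)] - [QMenergy(i) - QMenergy(0)] with
    the 0th conformer the group member of lowest QM energy. Rows with a
    non-finite FF energy or |ddE| beyond ``pathology_threshold`` are flagged
    pathological (excluded from summaries, retained for extrema reporting).
    """
    if group.n_records < 1:
        raise FFBenchError(f"group {group.key!r} has no records")
    ref = group.reference_index
    qm = group.qm_energies
    ff = np.array(
        [r.ff_results[ff_id].energy for r in group.records], dtype=float
    )
    de_qm = qm - qm[ref]
    ref_ff = ff[ref]
    de_ff = ff - ref_ff
    dde_vals = de_ff - de_qm
    rows = []
    for i, record in enumerate(group.records):
        pathological = (not math.isfinite(ff[i])) or (
            math.isfinite(dde_vals[i]) and abs(dde_vals[i]) > pathology_threshold
        ) or not math.isfinite(dde_vals[i])
        rows.append(
            {
                "key": group.key,
                "title": record.title,
                "conf_index": i,
                "ff_id": ff_id,
                "qm_energy": qm[i],
                "ff_energy": ff[i],
                "de_qm": de_qm[i],
                "de_ff": de_ff[i],
                "dde": dde_vals[i],
                "is_reference": i == ref,
                "pathological": bool(pathological) and i != ref,
            }
        )
    return pd.DataFrame(rows, columns=_TABLE_COLUMNS)


def energy_table(
    groups: Sequence[MoleculeGroup],
    ff_id: str,
    pathology_threshold: float = DEFAULT_PATHOLOGY_THRESHOLD,
) -> pd.DataFrame:
    """Concatenated ddE rows for all groups, one force field."""
    frames = [dde(g, ff_id, pathology_threshold) for g in groups]
    if not frames:
        return pd.DataFrame(columns=_TABLE_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def msd(values: Sequence[float], n: int) -> float:
    """Mean signed deviation over a molecule's non-reference conformers.

    ``values`` are the matched conformers' (dE_FF - dE_QM) with the
    reference excluded; ``n`` is the matched conformer count including the
    reference, so ``len(values) == n - 1``.
    """
    values = list(values)
    if n < 2:
        raise FFBenchError("MSD undefined for fewer than 2 conformers")
    if len(values) != n - 1:
        raise FFBenchError(
            f"expected {n - 1} non-reference values, got {len(values)}"
        )
    return float(sum(values) / (n - 1))


def msd_by_molecule(
    groups: Sequence[MoleculeGroup],
    matches: Mapping[str, "MatchResult"],  # noqa: F821 - forward ref
    ff_id: str,
    pathology_threshold: float = DEFAULT_PATHOLOGY_THRESHOLD,
) -> pd.DataFrame:
    """Per-molecule MSD over matched conformers for one force field.

    ``matches`` maps group key -> MatchResult for ``ff_id``. Matching acts
    as a filter: each surviving FF conformer f contributes its own record's
    deviation dE_FF(f) - dE_QM(f), both anchored at the group's reference
    conformer. The reference record (whose dE is identically 0) is
    excluded, as are pathological values (non-finite or beyond
    ``pathology_threshold``). Molecules with fewer than one non-reference
    matched conformer are skipped and logged.
    """
    rows = []
    for group in groups:
        match = matches.get(group.key)
        if match is None:
            continue
        ref = group.reference_index
        qm = group.qm_energies
        ff = np.array(
            [r.ff_results[ff_id].energy for r in group.records], dtype=float
        )
        de_qm = qm - qm[ref]
        de_ff = ff - ff[ref]
        values = [
            de_ff[f] - de_qm[f]
            for _q, f, _r in match.pairs
            if f != ref
            and math.isfinite(de_ff[f])
            and abs(de_ff[f] - de_qm[f]) <= pathology_threshold
        ]
        if not values:
            logger.info(
                "group %s: no non-reference matched conformers; MSD skipped",
                group.key,
            )
            continue
        rows.append(
            {
                "key": group.key,
                "ff_id": ff_id,
                "n_matched": len(values) + 1,
                "msd": msd(values, len(values) + 1),
            }
        )
    return pd.DataFrame(rows, columns=["key", "ff_id", "n_matched", "msd"])


def fraction_within(
    dde_values: Sequence[float],
    threshold: float = DEFAULT_WITHIN_THRESHOLD,
) -> tuple[float, float]:
    """Fraction of |ddE| <= threshold, with a binomial standard error."""
    values = np.asarray(list(dde_values), dtype=float)
    if values.size == 0:
        raise FFBenchError("fraction_within requires at least one value")
    if threshold <= 0:
        raise FFBenchError("threshold must be positive")
    p = float(np.mean(np.abs(values) <= threshold))
    se = float(np.sqrt(p * (1.0 - p) / values.size))
    return p, se


def extrema_summary(
    tables: Mapping[str, pd.DataFrame],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-force-field min/max ddE plus the pathological row listing.

    Min/max are taken over non-reference, non-pathological rows; the second
    frame lists every pathological row with its molecule key and title.
    """
    summary_rows = []
    patho_rows = []
    for ff_id, table in tables.items():
        body = table[~table["is_reference"]]
        clean = body[~body["pathological"]]
        summary_rows.append(
            {
                "ff_id": ff_id,
                "min_dde": float(clean["dde"].min()) if len(clean) else np.nan,
                "max_dde": float(clean["dde"].max()) if len(clean) else np.nan,
                "n_pathological": int(body["pathological"].sum()),
            }
        )
        for _, row in body[body["pathological"]].iterrows():
            patho_rows.append(
                {
                    "ff_id": ff_id,
                    "key": row["key"],
                    "title": row["title"],
                    "dde": row["dde"],
                    "ff_energy": row["ff_energy"],
                }
            )
    summary = pd.DataFrame(
        summary_rows, columns=["ff_id", "min_dde", "max_dde", "n_pathological"]
    )
    pathological = pd.DataFrame(
        patho_rows, columns=["ff_id", "key", "title", "dde", "ff_energy"]
    )
    return summary, pathological
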