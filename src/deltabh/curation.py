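"""Dataset curation: accept a reaction only if its IRC endpoints match.

The screening mirrors the standard sanity checks when rebuilding a
reaction dataset at a cheaper level of theory: a low-level transition-state
optimization must succeed, the two IRC endpoints must reproduce the
connectivity of the dataset reactant and product (adjacency-eigenvalue
fingerprints), and the re-optimized endpoints must be the same conformers
as the re-optimized dataset structures (weighted-adjacency fingerprints).
Records failing any stage are discarded with a reason code.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .constants import CONFORMATION_TOL, CONNECTIVITY_TOL
from .geometry import Geometry
from .molgraph import build_graph, same_conformation, same_connectivity


class Reason(str, Enum):
    OK = "ok"
    TS_OPT_FAILED = "ts_opt_failed"
    CONNECTIVITY_MISMATCH = "connectivity_mismatch"
    CONFORMATION_MISMATCH = "conformation_mismatch"


@dataclass
class RawRecord:
    """Inputs to the curation decision for one reaction.

    TS optimization and IRC integration are upstream quantum-chemistry
    steps; here they are represented by the ``ts_opt_ok`` flag and the four
    endpoint geometries.  ``opt_*`` fields hold the low-level re-optimized
    structures used for the conformer comparison.
    """

    dft_reactant: Geometry
    dft_product: Geometry
    ts_opt_ok: bool
    irc_fwd_endpoint: Geometry | None = None
    irc_rev_endpoint: Geometry | None = None
    opt_endpoint_fwd: Geometry | None = None
    opt_endpoint_rev: Geometry | None = None
    opt_dataset_reactant: Geometry | None = None
    opt_dataset_product: Geometry | None = None
    record_id: str = ""


@dataclass
class CurationReport:
    kept: bool
    reason: Reason
    # ("fwd", "rev") means fwd endpoint matched the reactant; None if discarded
    # before a direction could be assigned.
    direction_assignment: tuple[str, str] | None = None
    record_id: str = ""


class CurationDataError(ValueError):
    """Structural inconsistency inside a record (not a screening discard)."""


def _check_multiset(r: RawRecord) -> None:
    geoms = [
        g
        for g in (
            r.dft_reactant,
            r.dft_product,
            r.irc_fwd_endpoint,
            r.irc_rev_endpoint,
            r.opt_endpoint_fwd,
            r.opt_endpoint_rev,
            r.opt_dataset_reactant,
            r.opt_dataset_product,
        )
        if g is not None
    ]
    ref = sorted(geoms[0].symbols)
    for g in geoms[1:]:
        if sorted(g.symbols) != ref:
            raise CurationDataError(
                f"element multiset mismatch within record {r.record_id!r}"
            )


def curate_record(
    r: RawRecord,
    connectivity_tol: float = CONNECTIVITY_TOL,
    conformation_tol: float = CONFORMATION_TOL,
    bond_scale: float | None = None,
) -> CurationReport:
    """Run the screening flow for one record and report the decision."""
    _check_multiset(r)
    if not r.ts_opt_ok:
        return CurationReport(False, Reason.TS_OPT_FAILED, None, r.record_id)

    kwargs = {} if bond_scale is None else {"scale": bond_scale}
    g_fwd = build_graph(r.irc_fwd_endpoint, **kwargs)
    g_rev = build_graph(r.irc_rev_endpoint, **kwargs)
    g_react = build_graph(r.dft_reactant, **kwargs)
    g_prod = build_graph(r.dft_product, **kwargs)

    # Try both direction assignments; prefer fwd <-> reactant on a tie.
    assignment = None
    if same_connectivity(g_fwd, g_react, connectivity_tol) and same_connectivity(
        g_rev, g_prod, connectivity_tol
    ):
        assignment = ("fwd", "rev")
    elif same_connectivity(g_rev, g_react, connectivity_tol) and same_connectivity(
        g_fwd, g_prod, connectivity_tol
    ):
        assignment = ("rev", "fwd")
    if assignment is None:
        return CurationReport(False, Reason.CONNECTIVITY_MISMATCH, None, r.record_id)

    to_react, to_prod = assignment
    opt_by_dir = {"fwd": r.opt_endpoint_fwd, "rev": r.opt_endpoint_rev}
    ok_react = same_conformation(
        opt_by_dir[to_react], r.opt_dataset_reactant, conformation_tol
    )
    ok_prod = same_conformation(
        opt_by_dir[to_prod], r.opt_dataset_product, conformation_tol
    )
    if not (ok_react and ok_prod):
        return CurationReport(
            False, Reason.CONFORMATION_MISMATCH, assignment, r.record_id
        )
    return CurationReport(True, Reason.OK, assignment, r.record_id)


def curate_dataset(
    records: list[RawRecord], **tols
) -> tuple[list[RawRecord], list[CurationReport], dict[str, int]]:
    """Screen a list of records; returns kept records, reports, reason counts."""
    reports = [curate_record(r, **tols) for r in records]
    kept = [r for r, rep in zip(records, reports) if rep.kept]
    summary = Counter(rep.reason.value for rep in reports)
    counts = {reason.value: summary.get(reason.value, 0) for reason in Reason}
    return kept, reports, counts
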