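"""Combining target evidence across predictors, mature forms and databases.

Predictor evidence is combined by union (reducing the false-negative rate
of any single predictor), never by intersection by default; the two mature
forms of a single miRNA locus are likewise merged by union with provenance
tagged by mature form; validation databases are pooled because each holds
few interactions. All three operations are plain set unions, so they are
commutative, associative and idempotent.
"""

from __future__ import annotations

import logging

from .errors import ConfigurationError
from .types import IntegratedTargetSet, TargetPredictionTable, normalize_symbol

logger = logging.getLogger(__name__)


def integrate_predicted(
    tables: list[TargetPredictionTable],
    allow_multiple_mirnas: bool = False,
    mode: str = "union",
) -> IntegratedTargetSet:
    """Union of predicted targets across predictors, with per-gene provenance.

    All tables must describe the same miRNA locus unless
    ``allow_multiple_mirnas`` is set (used by :func:`merge_mature_forms`).
    ``mode='intersection'`` is available for sensitivity analysis only.
    """
    if not tables:
        raise ConfigurationError("need at least one target table")
    if mode not in ("union", "intersection"):
        raise ConfigurationError(f"unknown integration mode {mode!r}")
    mirnas = tuple(dict.fromkeys(t.mirna_id for t in tables))
    if len(mirnas) > 1 and not allow_multiple_mirnas:
        raise ConfigurationError(
            f"tables describe different miRNAs {mirnas}; merge mature forms explicitly"
        )
    provenance: dict[str, set[str]] = {}
    for t in tables:
        for g in t.targets:
            provenance.setdefault(g, set()).add(t.source)
    if mode == "intersection":
        keep = set.intersection(*[set(t.targets) for t in tables])
        provenance = {g: s for g, s in provenance.items() if g in keep}
    return IntegratedTargetSet(
        mirna_ids=mirnas,
        targets=frozenset(provenance),
        provenance={g: frozenset(s) for g, s in provenance.items()},
    )


def merge_mature_forms(
    set_a: IntegratedTargetSet, set_b: IntegratedTargetSet
) -> IntegratedTargetSet:
    """Union the target sets of two mature forms of one miRNA locus.

    Provenance entries are suffixed with the mature form they came from
    (e.g. ``predictorA@hsa-miR-5582-3p``).
    """
    provenance: dict[str, set[str]] = {}
    for part in (set_a, set_b):
        tag = "+".join(part.mirna_ids)
        for g, srcs in part.provenance.items():
            provenance.setdefault(g, set()).update(f"{s}@{tag}" for s in srcs)
    return IntegratedTargetSet(
        mirna_ids=set_a.mirna_ids + set_b.mirna_ids,
        targets=frozenset(provenance),
        provenance={g: frozenset(s) for g, s in provenance.items()},
        validated=set_a.validated | set_b.validated,
    )


def integrate_validated(tables: list[TargetPredictionTable]) -> frozenset[str]:
    """Pool validated interactions from up to three databases (union).

    The result only annotates downstream outputs (validated flags); it
    never gates the analysis.
    """
    if len(tables) > 3:
        raise ConfigurationError("at most three validation databases expected")
    out: set[str] = set()
    for t in tables:
        out.update(t.targets)
    return frozenset(out)


def annotate_validated(
    integrated: IntegratedTargetSet, validated: frozenset[str]
) -> IntegratedTargetSet:
    """Attach validation flags to an integrated set (non-destructive)."""
    return IntegratedTargetSet(
        mirna_ids=integrated.mirna_ids,
        targets=integrated.targets,
        provenance=integrated.provenance,
        validated=validated & integrated.targets,
    )


def check_host_self_target(
    integrated: IntegratedTargetSet, host_gene: str, mode: str = "warn"
) -> tuple[bool, IntegratedTargetSet]:
    """Test whether the host gene appears among its own miRNA's targets.

    Returns (was_present, possibly-filtered set). ``mode='remove'`` drops
    the host gene; ``'warn'`` keeps it and logs. In the real data none of
    the host genes is a predicted target of its own intronic miRNA, so a
    hit usually indicates an input mix-up.
    """
    if mode not in ("warn", "remove"):
        raise ConfigurationError(f"unknown self-target mode {mode!r}")
    host = normalize_symbol(host_gene)
    present = host in integrated.targets
    if not present:
        return False, integrated
    logger.warning("host gene %s appears among its own miRNA's targets", host)
    if mode == "warn":
        return True, integrated
    provenance = {g: s for g, s in integrated.provenance.items() if g != host}
    return True, IntegratedTargetSet(
        mirna_ids=integrated.mirna_ids,
        targets=frozenset(provenance),
        provenance=provenance,
        validated=integrated.validated - {host},
    )
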