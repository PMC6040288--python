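"""ADME threshold screening of compound tables.

Compounds are kept when they satisfy all three axes simultaneously:
oral bioavailability OB >= 15%, blood-brain-barrier score BBB >= -0.3,
and drug-likeness DL >= 0.1 (the defaults; all tunable).  A literature
whitelist can re-admit compounds that fail the thresholds, mirroring the
practice of adding pharmacologically well-documented constituents back
into a screen.  BBB scores additionally classify into non-penetrating
(< -0.3), moderate ([-0.3, +0.3], boundaries inclusive) and strong
(> +0.3) penetration categories.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from .core import CompoundTable, DataError, InteractionTable

logger = logging.getLogger("phytonet.adme")

__all__ = [
    "AdmeThresholds",
    "FilterAudit",
    "BBB_NON_PENETRATING",
    "BBB_MODERATE",
    "BBB_STRONG",
    "classify_bbb",
    "filter_compounds",
    "drop_targetless",
]

BBB_NON_PENETRATING = "non_penetrating"
BBB_MODERATE = "moderate"
BBB_STRONG = "strong"


@dataclass(frozen=True)
class AdmeThresholds:
    """Lower bounds on the three screening axes."""

    ob_min: float = 15.0
    bbb_min: float = -0.3
    dl_min: float = 0.1

    def __post_init__(self) -> None:
        for name in ("ob_min", "bbb_min", "dl_min"):
            v = getattr(self, name)
            if math.isnan(v):
                raise DataError(f"{name} must not be NaN")

    def violations(self, ob: float, bbb: float, dl: float) -> list[str]:
        """Names of the axes a compound fails, in fixed (ob, bbb, dl) order."""
        out = []
        if ob < self.ob_min:
            out.append("ob")
        if bbb < self.bbb_min:
            out.append("bbb")
        if dl < self.dl_min:
            out.append("dl")
        return out


@dataclass
class FilterAudit:
    """Per-compound account of an ADME screen.

    ``violations`` maps every input compound id to the (possibly empty)
    list of failed axes; ``passed``/``failed`` partition the input;
    ``whitelisted_in`` lists failing compounds re-admitted by whitelist.
    """

    violations: dict[str, list[str]] = field(default_factory=dict)
    passed: list[str] = field(default_factory=list)
    failed: list[str] = field(default_factory=list)
    whitelisted_in: list[str] = field(default_factory=list)
    missing_whitelist: list[str] = field(default_factory=list)

    @property
    def n_input(self) -> int:
        return len(self.passed) + len(self.failed)

    def to_rows(self) -> list[dict]:
        rows = []
        for cid, viol in self.violations.items():
            rows.append(
                {
                    "id": cid,
                    "passed": cid in set(self.passed),
                    "violated": ",".join(viol),
                    "whitelisted_in": cid in set(self.whitelisted_in),
                }
            )
        return rows


def classify_bbb(bbb: float) -> str:
    """Categorize a blood-brain-barrier score.

    Below -0.3 is non-penetrating, -0.3 through +0.3 (inclusive) moderate,
    above +0.3 strong penetration.
    """
    if not math.isfinite(bbb):
        raise DataError(f"BBB score must be finite, got {bbb!r}")
    if bbb < -0.3:
        return BBB_NON_PENETRATING
    if bbb <= 0.3:
        return BBB_MODERATE
    return BBB_STRONG


def filter_compounds(
    table: CompoundTable,
    thresholds: AdmeThresholds | None = None,
    whitelist: set[str] | None = None,
) -> tuple[CompoundTable, FilterAudit]:
    """Screen ``table`` by the three ADME thresholds plus a whitelist.

    Returns the retained table (input order preserved; whitelisted
    records flagged) and a :class:`FilterAudit`.  Whitelisted compounds
    bypass all three thresholds; whitelist ids absent from the table are
    logged as warnings, not errors.
    """
    thresholds = thresholds or AdmeThresholds()
    whitelist = set(whitelist or ())
    audit = FilterAudit()

    missing = whitelist - set(table.ids)
    for cid in sorted(missing):
        logger.warning("whitelist id %r not present in compound table", cid)
    audit.missing_whitelist = sorted(missing)

    keep: list[str] = []
    for rec in table:
        viol = thresholds.violations(rec.ob, rec.bbb, rec.dl)
        audit.violations[rec.compound_id] = viol
        if not viol:
            audit.passed.append(rec.compound_id)
            keep.append(rec.compound_id)
        else:
            audit.failed.append(rec.compound_id)
            if rec.compound_id in whitelist:
                audit.whitelisted_in.append(rec.compound_id)
                keep.append(rec.compound_id)
    out = table.subset(keep).with_whitelisted(
        set(audit.whitelisted_in) | (whitelist & set(keep))
    )
    logger.info(
        "ADME screen: %d in, %d passed, %d failed, %d whitelisted back in",
        len(table), len(audit.passed), len(audit.failed), len(audit.whitelisted_in),
    )
    return out, audit


def drop_targetless(
    table: CompoundTable, interactions: InteractionTable
) -> tuple[CompoundTable, list[str]]:
    """Remove compounds with no interaction evidence.

    Returns the retained table and the removed ids in input order.
    """
    with_targets = interactions.compound_ids
    removed = [cid for cid in table.ids if cid not in with_targets]
    if removed:
        logger.info("removed %d compound(s) with no target information", len(removed))
    return table.subset(cid for cid in table.ids if cid in with_targets), removed
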