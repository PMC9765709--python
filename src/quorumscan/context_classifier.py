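"""Genomic-context assignment and signaling-role classification.

Context: plasmid / phage-plasmid from the replicon-level MGE label,
prophage when the receptor gene is fully contained in a prophage interval,
chromosome otherwise. Role: eavesdropper (no propeptide), chatterer
(at least two identical mature copies, within one propeptide or across
sibling genes), multi-message (at least two distinct matures), single.
Chatterer takes precedence when both conditions hold.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .propeptide_finder import PropeptideCall
from .receptor_search import ReceptorHit
from .repeat_analysis import RepeatReport

ROLES = ("eavesdropper", "single", "chatterer", "multi-message")
_TYPE_TO_CONTEXT = {"plasmid": "plasmid", "phage_plasmid": "phage-plasmid"}


@dataclasses.dataclass
class QSSystemRecord:
    receptor: ReceptorHit
    propeptides: list[PropeptideCall]
    context: str
    role: str = ""
    genus: str | None = None

    @property
    def family(self) -> str:
        return self.receptor.assigned_family or self.receptor.family


def validate_mge_table(mge: pd.DataFrame) -> None:
    """Reject overlapping prophage intervals on a single replicon."""
    pro = mge[mge["type"] == "prophage"]
    for replicon, group in pro.groupby("replicon_id"):
        ivs = sorted(zip(group["start"].astype(int), group["end"].astype(int)))
        for (s0, e0), (s1, _) in zip(ivs, ivs[1:]):
            if s1 < e0:
                raise ValueError(
                    f"overlapping prophage intervals on {replicon}: "
                    f"[{s0}, {e0}) and starting at {s1}"
                )


def assign_context(
    gene: Mapping,
    mge: pd.DataFrame,
    replicons: Iterable[str] | None = None,
) -> str:
    """Context label for a gene; full containment is required for prophage
    membership. ``replicons``, when given, defines the known-replicon set."""
    validate_mge_table(mge)
    rid = str(gene["replicon_id"])
    if replicons is not None and rid not in set(replicons):
        raise ValueError(f"gene on unknown replicon {rid!r}")
    level = mge[
        (mge["replicon_id"] == rid) & (mge["type"].isin(_TYPE_TO_CONTEXT))
    ]
    if len(level):
        return _TYPE_TO_CONTEXT[str(level.iloc[0]["type"])]
    start, end = int(gene["start"]), int(gene["end"])
    pro = mge[(mge["replicon_id"] == rid) & (mge["type"] == "prophage")]
    for _, row in pro.iterrows():
        if int(row["start"]) <= start and end <= int(row["end"]):
            return "prophage"
    return "chromosome"


def classify_role(
    system: QSSystemRecord, reports: Sequence[RepeatReport] | None = None
) -> str:
    """Role from the mature-copy structure of the system's propeptides.

    ``reports`` aligns with ``system.propeptides``; when omitted, each call
    counts as a single copy of its mature peptide.
    """
    if not system.propeptides:
        return "eavesdropper"
    messages: Counter[str] = Counter()
    if reports is None:
        reports = [None] * len(system.propeptides)  # type: ignore[list-item]
    for call, report in zip(system.propeptides, reports):
        if report is None:
            messages[call.mature[-5:]] += 1
        else:
            for copy in report.copies:
                messages[copy] += 1
    if max(messages.values()) >= 2:
        return "chatterer"
    if len(messages) >= 2:
        return "multi-message"
    return "single"


def build_systems(
    hits: Sequence[ReceptorHit],
    calls_by_receptor: Mapping[str, Sequence[PropeptideCall]],
    mge: pd.DataFrame,
    reports_by_receptor: Mapping[str, Sequence[RepeatReport]] | None = None,
    replicons: Iterable[str] | None = None,
    genus_map: Mapping[str, str] | None = None,
) -> list[QSSystemRecord]:
    """Assemble classified system records from pipeline outputs."""
    systems = []
    for hit in hits:
        calls = list(calls_by_receptor.get(hit.protein_id, []))
        gene = {"replicon_id": hit.replicon_id, "start": hit.start, "end": hit.end}
        context = assign_context(gene, mge, replicons=replicons)
        record = QSSystemRecord(
            receptor=hit,
            propeptides=calls,
            context=context,
            genus=genus_map.get(hit.protein_id) if genus_map else None,
        )
        reports = (
            reports_by_receptor.get(hit.protein_id)
            if reports_by_receptor is not None
            else None
        )
        record.role = classify_role(record, reports)
        systems.append(record)
    return systems


def summarize(
    systems: Sequence[QSSystemRecord], normalize_by_genus: bool = False
) -> pd.DataFrame:
    """Family x context table: n, % with >= 1 propeptide, % eavesdropper.

    With ``normalize_by_genus`` each genus contributes equal weight to the
    percentages (systems lacking a genus each count as their own genus).
    """
    if not systems:
        return pd.DataFrame(
            columns=["family", "context", "n", "pct_with_propeptide", "pct_eavesdropper"]
        )
    rows = []
    for s in systems:
        rows.append(
            dict(
                family=s.family,
                context=s.context,
                genus=s.genus if s.genus else f"__{s.receptor.protein_id}",
                has_propeptide=bool(s.propeptides),
                eavesdropper=s.role == "eavesdropper",
            )
        )
    df = pd.DataFrame(rows)
    out = []
    for (family, context), grp in df.groupby(["family", "context"]):
        if normalize_by_genus:
            per_genus = grp.groupby("genus")[["has_propeptide", "eavesdropper"]].mean()
            has_pct = 100.0 * per_genus["has_propeptide"].mean()
            eav_pct = 100.0 * per_genus["eavesdropper"].mean()
        else:
            has_pct = 100.0 * grp["has_propeptide"].mean()
            eav_pct = 100.0 * grp["eavesdropper"].mean()
        out.append(
            dict(
                family=family,
                context=context,
                n=len(grp),
                pct_with_propeptide=has_pct,
                pct_eavesdropper=eav_pct,
            )
        )
    result = pd.DataFrame(out).sort_values(["family", "context"]).reset_index(drop=True)
    assert int(result["n"].sum()) == len(systems)
    return result


def systems_to_frame(systems: Sequence[QSSystemRecord]) -> pd.DataFrame:
    rows = []
    for s in systems:
        rows.append(
            dict(
                receptor_id=s.receptor.protein_id,
                family=s.family,
                replicon_id=s.receptor.replicon_id,
                context=s.context,
                role=s.role,
                n_propeptides=len(s.propeptides),
                matures=";".join(c.mature for c in s.propeptides),
            )
        )
    return pd.DataFrame(rows)
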