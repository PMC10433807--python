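"""Detection and accounting of ASV "transfer events" within mother-infant dyads.

A potential transfer event is the detection of the same amplicon sequence
variant (ASV) at or above a relative-abundance threshold in a mother's
vaginal microbiome and in at least one stool microbiome from her infant.
Shared presence does not prove transmission, hence "potential"; the
threshold (0.1% in the motivating study) suppresses spurious sharing of
low-abundance variants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import DyadCohort, FeatureTable, TaxonomyTable

CATEGORIES = ("ten_day_only", "three_month_only", "both")


@dataclass(frozen=True)
class TransferEvent:
    """One (dyad, ASV) pair passing the maternal and infant abundance gates."""

    dyad_id: str
    asv_id: str
    category: str  # ten_day_only | three_month_only | both
    maternal_rel_abundance: float
    infant_rel_abundances: tuple[tuple[str, float], ...]  # (time_point, ra)


@dataclass(frozen=True)
class DyadTransferCount:
    dyad_id: str
    n_transfer_events: int
    delivery_mode: str
    ip_antibiotics: str


@dataclass(frozen=True)
class TaxonTransferSummary:
    """Per-ASV transfer accounting, mirroring the study's summary tables."""

    asv_id: str
    taxon: str
    pct_identity: float
    n_maternal_above_threshold: int
    n_transfers: int
    n_both: int
    n_ten_day: int
    n_three_month: int

    @property
    def transfer_rate(self) -> float:
        if self.n_maternal_above_threshold == 0:
            return 0.0
        return self.n_transfers / self.n_maternal_above_threshold


def _passes(value: float, threshold: float, inclusive: bool) -> bool:
    return value >= threshold if inclusive else value > threshold


def detect_transfers(
    cohort: DyadCohort,
    table: FeatureTable,
    threshold: float = 0.001,
    inclusive: bool = True,
) -> list[TransferEvent]:
    """Find all (dyad, ASV) transfer events at a relative-abundance threshold.

    The gate is symmetric: the ASV must reach the threshold in the maternal
    sample AND in at least one available infant sample. The comparison is
    inclusive (>=) by default; ``inclusive=False`` switches to strict (>).
    One event is emitted per (dyad, ASV) regardless of how many infant
    samples pass; ``category`` records which time points passed.
    """
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    ra = table.rel_abundance
    zero_total = set(table.zero_total_samples)
    events: list[TransferEvent] = []
    for dyad_id in sorted(cohort.dyads):
        dyad = cohort.dyads[dyad_id]
        if dyad.maternal in zero_total:
            continue
        maternal_ra = ra.loc[dyad.maternal]
        mask = (
            maternal_ra.values >= threshold
            if inclusive
            else maternal_ra.values > threshold
        )
        maternal_pass = maternal_ra.index[mask]
        infant_samples = {
            tp: s for tp, s in dyad.infant_samples.items() if s not in zero_total
        }
        if not infant_samples:
            continue
        for asv in maternal_pass:
            passing = [
                tp
                for tp, s in infant_samples.items()
                if _passes(ra.at[s, asv], threshold, inclusive)
            ]
            if not passing:
                continue
            if "10_days" in passing and "3_months" in passing:
                cat = "both"
            elif "10_days" in passing:
                cat = "ten_day_only"
            else:
                cat = "three_month_only"
            events.append(
                TransferEvent(
                    dyad_id=dyad_id,
                    asv_id=str(asv),
                    category=cat,
                    maternal_rel_abundance=float(maternal_ra[asv]),
                    infant_rel_abundances=tuple(
                        (tp, float(ra.at[s, asv]))
                        for tp, s in sorted(infant_samples.items())
                    ),
                )
            )
    return events


def count_per_dyad(
    events: list[TransferEvent], cohort: DyadCohort
) -> list[DyadTransferCount]:
    """Per-dyad event counts; every cohort dyad appears, zeros included."""
    tally: dict[str, int] = {d: 0 for d in cohort.dyads}
    for ev in events:
        if ev.dyad_id not in tally:
            raise ValueError(f"event dyad {ev.dyad_id!r} not in cohort")
        tally[ev.dyad_id] += 1
    return [
        DyadTransferCount(
            dyad_id=d,
            n_transfer_events=tally[d],
            delivery_mode=cohort.dyads[d].delivery_mode,
            ip_antibiotics=cohort.dyads[d].ip_antibiotics,
        )
        for d in sorted(tally)
    ]


def summarize_by_asv(
    events: list[TransferEvent],
    table: FeatureTable,
    taxonomy: TaxonomyTable | None,
    cohort: DyadCohort,
    threshold: float = 0.001,
    inclusive: bool = True,
) -> list[TaxonTransferSummary]:
    """Per-ASV transfer accounting over the whole cohort.

    ``n_maternal_above_threshold`` counts maternal samples (one per dyad)
    where the ASV clears the gate — the transfer-rate denominator. Rows are
    sorted by n_transfers descending, ties broken by ASV identifier.
    """
    ra = table.rel_abundance
    maternal_samples = [
        cohort.dyads[d].maternal
        for d in sorted(cohort.dyads)
        if cohort.dyads[d].maternal not in set(table.zero_total_samples)
    ]
    sub = ra.loc[maternal_samples]
    mat = sub.values >= threshold if inclusive else sub.values > threshold
    n_maternal = pd.Series(mat.sum(axis=0), index=sub.columns)

    by_asv: dict[str, dict[str, int]] = {}
    for ev in events:
        d = by_asv.setdefault(ev.asv_id, {"both": 0, "ten_day_only": 0, "three_month_only": 0})
        d[ev.category] += 1
    rows = []
    for asv, cats in by_asv.items():
        n_tr = sum(cats.values())
        rows.append(
            TaxonTransferSummary(
                asv_id=asv,
                taxon=taxonomy.label(asv) if taxonomy else "unassigned",
                pct_identity=taxonomy.pct_identity(asv) if taxonomy else float("nan"),
                n_maternal_above_threshold=int(n_maternal.get(asv, 0)),
                n_transfers=n_tr,
                n_both=cats["both"],
                n_ten_day=cats["ten_day_only"],
                n_three_month=cats["three_month_only"],
            )
        )
    rows.sort(key=lambda r: (-r.n_transfers, r.asv_id))
    return rows


def aggregate_summaries(rows: list[TaxonTransferSummary]) -> dict[str, float]:
    """Totals over a collection of per-ASV summary rows.

    This is the accounting behind the study's table footers: total maternal
    detections, total transfers, the pooled transfer rate and the category
    split.
    """
    n_mat = sum(r.n_maternal_above_threshold for r in rows)
    n_tr = sum(r.n_transfers for r in rows)
    return {
        "n_maternal_above_threshold": n_mat,
        "n_transfers": n_tr,
        "transfer_rate": (n_tr / n_mat) if n_mat else 0.0,
        "n_both": sum(r.n_both for r in rows),
        "n_ten_day": sum(r.n_ten_day for r in rows),
        "n_three_month": sum(r.n_three_month for r in rows),
    }


def aggregate_by_genus(rows: list[TaxonTransferSummary]) -> dict[str, dict[str, float]]:
    """Aggregate per-ASV rows to genus level via taxon-label prefix."""
    out: dict[str, list[TaxonTransferSummary]] = {}
    for r in rows:
        genus = r.taxon.split()[0] if r.taxon else "unassigned"
        out.setdefault(genus, []).append(r)
    return {g: aggregate_summaries(rs) for g, rs in sorted(out.items())}


def concordance(
    per_dyad_shared: dict[str, bool], per_dyad_strain_identical: dict[str, bool]
) -> tuple[float, np.ndarray]:
    """Agreement between ASV-sharing calls and strain-identity calls.

    Returns the fraction of dyads where the two boolean calls agree and the
    full 2x2 cross-tabulation ``[[TT, TF], [FT, FF]]`` (rows: shared ASV
    yes/no; columns: identical strain yes/no).
    """
    if set(per_dyad_shared) != set(per_dyad_strain_identical):
        raise ValueError("dyad sets differ between the two inputs")
    if not per_dyad_shared:
        raise ValueError("empty dyad set")
    tab = np.zeros((2, 2), dtype=int)
    agree = 0
    for d, shared in per_dyad_shared.items():
        ident = per_dyad_strain_identical[d]
        tab[0 if shared else 1, 0 if ident else 1] += 1
        agree += shared == ident
    return agree / len(per_dyad_shared), tab


def events_to_frame(events: list[TransferEvent]) -> pd.DataFrame:
    """Events as a tidy DataFrame (one row per event)."""
    rows = []
    for ev in events:
        ra = dict(ev.infant_rel_abundances)
        rows.append(
            {
                "dyad_id": ev.dyad_id,
                "asv_id": ev.asv_id,
                "category": ev.category,
                "maternal_ra": ev.maternal_rel_abundance,
                "infant10_ra": ra.get("10_days", float("nan")),
                "infant3m_ra": ra.get("3_months", float("nan")),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["dyad_id", "asv_id", "category", "maternal_ra", "infant10_ra", "infant3m_ra"],
    )


def summaries_to_frame(rows: list[TaxonTransferSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "asv_id": r.asv_id,
                "taxon": r.taxon,
                "pct_identity": r.pct_identity,
                "n_maternal": r.n_maternal_above_threshold,
                "n_transfers": r.n_transfers,
                "n_both": r.n_both,
                "n_10d": r.n_ten_day,
                "n_3mo": r.n_three_month,
                "transfer_rate": r.transfer_rate,
            }
            for r in rows
        ],
        columns=[
            "asv_id", "taxon", "pct_identity", "n_maternal", "n_transfers",
            "n_both", "n_10d", "n_3mo", "transfer_rate",
        ],
    )
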