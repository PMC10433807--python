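import numpy as np
import pandas as pd
import pytest

from dyadtrace import FeatureTable, SampleMeta, build_cohort


@pytest.fixture
def tiny_table() -> FeatureTable:
    """2 samples x 2 ASVs with counts [[900, 100], [0, 50]]."""
    return FeatureTable(
        counts=pd.DataFrame(
            [[900, 100], [0, 50]], index=["s1", "s2"], columns=["a1", "a2"]
        )
    )


@pytest.fixture
def small_cohort():
    """3 dyads x 4 ASVs with hand-chosen abundances around a 0.1% gate.

    d1: ASV a0 at 0.2% in mother, 0.15% at 10 days, absent at 3 months.
    d2: ASV a1 at 0.05% in mother (below gate), 5% in infant.
    d3: ASV a2 at 1% in mother and both infant samples.
    """
    depth = 20_000
    rows = {}

    def counts(filler, **ra):
        # filler columns differ between maternal (a3) and infant (a4)
        # samples so the filler itself never constitutes a shared ASV
        v = np.zeros(5, dtype=int)
        for asv, frac in ra.items():
            v[int(asv[1])] = round(frac * depth)
        v[filler] = depth - v.sum()
        return v

    rows["d1_M"] = counts(3, a0=0.002)
    rows["d1_I10"] = counts(4, a0=0.0015)
    rows["d1_I3M"] = counts(4)
    rows["d2_M"] = counts(3, a1=0.0005)
    rows["d2_I10"] = counts(4, a1=0.05)
    rows["d3_M"] = counts(3, a2=0.01)
    rows["d3_I10"] = counts(4, a2=0.01)
    rows["d3_I3M"] = counts(4, a2=0.01)
    table = FeatureTable(
        counts=pd.DataFrame.from_dict(
            rows, orient="index", columns=["a0", "a1", "a2", "a3", "a4"]
        )
    )
    meta = []
    for dyad in ("d1", "d2", "d3"):
        mode = {"d1": "vaginal", "d2": "elective_CS", "d3": "emergency_CS"}[dyad]
        meta.append(SampleMeta(f"{dyad}_M", dyad, "maternal_vaginal", "delivery", mode, "exposed"))
        meta.append(SampleMeta(f"{dyad}_I10", dyad, "infant_stool", "10_days", mode, "exposed"))
        if f"{dyad}_I3M" in rows:
            meta.append(SampleMeta(f"{dyad}_I3M", dyad, "infant_stool", "3_months", mode, "exposed"))
    cohort = build_cohort(table, meta)
    return table, meta, cohort


def brute_force_transfers(cohort, table, threshold, inclusive=True):
    """Independent triple-loop oracle for transfer detection."""
    ra = table.rel_abundance
    zero = set(table.zero_total_samples)
    found = {}
    for dyad_id, dyad in cohort.dyads.items():
        if dyad.maternal in zero:
            continue
        for asv in table.asv_ids:
            m = ra.at[dyad.maternal, asv]
            m_ok = m >= threshold if inclusive else m > threshold
            if not m_ok:
                continue
            passing = []
            for tp, sid in dyad.infant_samples.items():
                if sid in zero:
                    continue
                v = ra.at[sid, asv]
                if (v >= threshold) if inclusive else (v > threshold):
                    passing.append(tp)
            if passing:
                if set(passing) == {"10_days", "3_months"}:
                    cat = "both"
                elif passing == ["10_days"]:
                    cat = "ten_day_only"
                else:
                    cat = "three_month_only"
                found[(dyad_id, asv)] = cat
    return found
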