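"""Cytological exchange-point mapping: FLA values, arm-interval histograms
and chromosome-type classification.

Measurements come from metaphase images: for each chromosomal exchange
point (EP) the distance (μm) to the telomere of its arm, and the arm's
total length.  FLA (fractional length of the arm) places the EP on a
0 (telomere) to 100 (centromere) scale, independent of magnification and
chromosome condensation.  EPs are binned into fixed-percent arm intervals
(default 5%), and each chromosome copy is classified into one of eight
parental/recombinant types from its centromere origin and the number of
EPs per arm; two or more EPs on a single arm fall outside the eight types
and are reported as ``other`` with an annotation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

ARMS = ("short", "long")


@dataclass(frozen=True)
class ArmMeasurement:
    """Measured arm with its exchange-point distances (μm to telomere)."""

    chromosome_id: str
    arm: str
    arm_length_um: float
    ep_distances_um: tuple[float, ...] = ()

    def __post_init__(self):
        if self.arm not in ARMS:
            raise ValueError(f"arm must be one of {ARMS}, got {self.arm!r}")
        if self.arm_length_um <= 0:
            raise ValueError("arm_length_um must be > 0")
        for d in self.ep_distances_um:
            if not 0 <= d <= self.arm_length_um:
                raise ValueError(
                    f"EP distance {d} outside [0, {self.arm_length_um}] μm"
                )


@dataclass(frozen=True)
class FlaValue:
    """An exchange point as percent of its arm (0 telomere, 100 centromere)."""

    fla: float
    arm: str
    interval_index: int


@dataclass(frozen=True)
class ChromosomeTypeCall:
    centromere_origin: str  # 'B' or 'M'
    eps_short: int
    eps_long: int
    code: str  # B1..B4 / M1..M4 / other
    annotation: str = ""


def compute_fla(distance_um: float, arm_length_um: float, arm: str = "long",
                bin_width_percent: float = 5.0) -> FlaValue:
    """FLA = 100 x distance / arm length."""
    if arm_length_um <= 0:
        raise ValueError("arm_length_um must be > 0")
    if not 0 <= distance_um <= arm_length_um:
        raise ValueError(
            f"distance ({distance_um} μm) outside [0, {arm_length_um}] μm arm"
        )
    fla = 100.0 * distance_um / arm_length_um
    return FlaValue(fla, arm, bin_fla(fla, bin_width_percent))


def bin_fla(fla: float, bin_width_percent: float = 5.0) -> int:
    """Interval index floor(fla / width), telomere -> centromere; FLA 100
    lands in the last interval so centromere-adjacent EPs stay countable."""
    if not 0 <= fla <= 100:
        raise ValueError(f"fla must be in [0, 100], got {fla}")
    n_bins = int(np.ceil(100.0 / bin_width_percent))
    return min(int(fla // bin_width_percent), n_bins - 1)


def classify_chromosome_type(centromere_origin: str, eps_short: int,
                             eps_long: int, short_arm_digit: int = 2) -> ChromosomeTypeCall:
    """Eight-type classification of a chromosome copy.

    The letter is the haplotype spanning the centromere; the digit is
    1 = parental (no EP), 2 = one EP on the short arm, 3 = one EP on the
    long arm, 4 = one EP on each arm (``short_arm_digit=3`` swaps the arm
    convention for digits 2/3).  Any arm with >= 2 EPs is outside the eight
    types -> ``other``, annotated as a same-arm double crossover.
    """
    if centromere_origin not in ("B", "M"):
        raise ValueError("centromere_origin must be 'B' or 'M'")
    if eps_short < 0 or eps_long < 0:
        raise ValueError("EP counts must be >= 0")
    if eps_short >= 2 or eps_long >= 2:
        return ChromosomeTypeCall(centromere_origin, eps_short, eps_long,
                                  "other", "double-CO-same-arm")
    long_arm_digit = 5 - short_arm_digit  # the other of {2, 3}
    if eps_short == 0 and eps_long == 0:
        digit = 1
    elif eps_short == 1 and eps_long == 0:
        digit = short_arm_digit
    elif eps_short == 0 and eps_long == 1:
        digit = long_arm_digit
    else:
        digit = 4
    return ChromosomeTypeCall(centromere_origin, eps_short, eps_long,
                              f"{centromere_origin}{digit}")


def ep_histogram(records: pd.DataFrame, bin_width_percent: float = 5.0) -> pd.DataFrame:
    """Per-interval EP counts, separately per haplotype/arm and combined.

    ``records`` needs columns ``haplotype``, ``arm``, ``fla``.  Returns a
    long-format frame (haplotype, arm, interval, count) where haplotype
    ``combined`` sums over haplotypes; intervals with zero EPs are included.
    """
    n_bins = int(np.ceil(100.0 / bin_width_percent))
    groups = list(records["haplotype"].unique()) + ["combined"]
    rows = []
    for group in groups:
        sub = records if group == "combined" else records[records["haplotype"] == group]
        for arm in ARMS:
            counts = np.zeros(n_bins, dtype=np.int64)
            for fla in sub.loc[sub["arm"] == arm, "fla"]:
                counts[bin_fla(float(fla), bin_width_percent)] += 1
            for i in range(n_bins):
                rows.append({"haplotype": group, "arm": arm, "interval": i,
                             "count": int(counts[i])})
    return pd.DataFrame(rows)


def analyze_measurements(df: pd.DataFrame, bin_width_percent: float = 5.0,
                         short_arm_digit: int = 2) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Full cytology pass over a measurement table.

    Input columns: plant_id, chromosome_copy, centromere_origin, arm,
    arm_length_um, ep_distance_um (empty/NaN for arms without an EP; one
    row per EP).  Returns (fla_table, type_calls, histogram).
    """
    fla_rows = []
    for _, r in df.iterrows():
        if pd.isna(r.get("ep_distance_um")):
            continue
        v = compute_fla(float(r["ep_distance_um"]), float(r["arm_length_um"]),
                        arm=str(r["arm"]), bin_width_percent=bin_width_percent)
        fla_rows.append({
            "plant_id": r["plant_id"],
            "chromosome_copy": r["chromosome_copy"],
            "haplotype": r["centromere_origin"],
            "arm": v.arm,
            "fla": round(v.fla, 2),
            "interval": v.interval_index,
        })
    fla_table = pd.DataFrame(fla_rows)

    call_rows = []
    for (plant, copy_id), sub in df.groupby(["plant_id", "chromosome_copy"]):
        origin = str(sub["centromere_origin"].iloc[0])
        n_short = int(sub[(sub["arm"] == "short") & sub["ep_distance_um"].notna()].shape[0])
        n_long = int(sub[(sub["arm"] == "long") & sub["ep_distance_um"].notna()].shape[0])
        call = classify_chromosome_type(origin, n_short, n_long, short_arm_digit)
        call_rows.append({
            "plant_id": plant, "chromosome_copy": copy_id,
            "centromere_origin": origin, "eps_short": n_short,
            "eps_long": n_long, "code": call.code, "annotation": call.annotation,
        })
    type_calls = pd.DataFrame(call_rows)
    hist = (
        ep_histogram(fla_table, bin_width_percent)
        if not fla_table.empty
        else pd.DataFrame(columns=["haplotype", "arm", "interval", "count"])
    )
    return fla_table, type_calls, hist
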