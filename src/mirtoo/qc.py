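"""RT/qPCR quality control and cDNA dilution decisions.

Before a sample enters ddPCR profiling, two qPCR control assays are run on
its cDNA: UniSp6 (an RNA spike-in added at reverse transcription, whose Ct
reflects RT efficiency) and SNORD44 (an endogenous small nucleolar RNA whose
Ct reflects RNA integrity/amplifiability). The SNORD44 Ct decides how much
the cDNA is diluted before the ddPCR plate, preventing droplet saturation
for high-input samples and signal dropout for low-input ones:

* Ct in [24, 30]  -> dilute 1:50
* Ct < 24         -> dilute 1:100 (configurable up to 1:200)
* Ct > 30         -> repeat the RT with undiluted RNA and re-run QC

Whatever the dilution, the miR-21-5p and UniSp6 wells receive an additional
1:10 dilution (both targets are far more abundant than the rest of the
panel). UniSp6 Ct is recorded but carries no numeric acceptance window, so
it never blocks a sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import pandas as pd

#: Wells always further diluted 1:10 on the ddPCR plate.
EXTRA_DILUTION_WELLS: tuple[str, ...] = ("miR-21-5p", "UniSp6")

#: SNORD44 Ct band (inclusive) mapped to the standard 1:50 dilution.
CT_BAND_LOW = 24.0
CT_BAND_HIGH = 30.0


class QCIncompleteError(ValueError):
    """A required control Ct is missing, so no dilution decision is possible."""


@dataclass(frozen=True)
class QCRecord:
    """Per-sample qPCR QC readout (Ct values in cycles)."""

    sample_id: str
    snord44_ct: float | None
    unisp6_ct: float | None = None
    fluorescence_threshold: float = 160.0

    def __post_init__(self) -> None:
        for name in ("snord44_ct", "unisp6_ct"):
            ct = getattr(self, name)
            if ct is not None and not (math.isfinite(ct) and ct > 0):
                raise ValueError(f"{name} must be finite and > 0, got {ct}")


@dataclass(frozen=True)
class DilutionDecision:
    action: Literal["dilute", "repeat_rt"]
    dilution_factor: int | None = None
    extra_dilution_wells: tuple[str, ...] = EXTRA_DILUTION_WELLS

    def __post_init__(self) -> None:
        if self.action == "repeat_rt" and self.dilution_factor is not None:
            raise ValueError("repeat_rt carries no dilution factor")
        if self.action == "dilute" and self.dilution_factor is None:
            raise ValueError("dilute requires a dilution factor")


def choose_dilution(record: QCRecord, low_ct_factor: int = 100) -> DilutionDecision:
    """Map a SNORD44 Ct to the cDNA dilution decision.

    ``low_ct_factor`` (default 1:100) is the dilution for high-input samples
    (Ct < 24); any fold in 100-200 is admissible. Both band boundaries are
    inclusive in the 1:50 band.
    """
    if record.snord44_ct is None or (
        isinstance(record.snord44_ct, float) and math.isnan(record.snord44_ct)
    ):
        raise QCIncompleteError(
            f"sample {record.sample_id}: SNORD44 Ct missing, QC incomplete"
        )
    if not 100 <= low_ct_factor <= 200:
        raise ValueError("low_ct_factor must be in [100, 200]")
    ct = float(record.snord44_ct)
    if ct > CT_BAND_HIGH:
        return DilutionDecision(action="repeat_rt")
    if ct < CT_BAND_LOW:
        return DilutionDecision(action="dilute", dilution_factor=low_ct_factor)
    return DilutionDecision(action="dilute", dilution_factor=50)


# -------------------------------------------------------------------- I/O
def read_qc_records(path: str | Path) -> list[QCRecord]:
    """Read QC records from TSV/CSV (sample_id, unisp6_ct, snord44_ct)."""
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, na_values=["NA", ""], dtype={"sample_id": str})
    records = []
    for row in df.itertuples(index=False):
        records.append(
            QCRecord(
                sample_id=row.sample_id,
                snord44_ct=None if pd.isna(row.snord44_ct) else float(row.snord44_ct),
                unisp6_ct=None if pd.isna(row.unisp6_ct) else float(row.unisp6_ct),
            )
        )
    return records


def decisions_table(records: list[QCRecord], low_ct_factor: int = 100) -> pd.DataFrame:
    """Apply :func:`choose_dilution` to all records, returning a tidy table.

    Samples with missing SNORD44 Ct are reported with action ``qc_incomplete``
    rather than raising, so one bad record does not abort a batch.
    """
    rows = []
    for rec in records:
        try:
            dec = choose_dilution(rec, low_ct_factor=low_ct_factor)
            rows.append(
                {
                    "sample_id": rec.sample_id,
                    "snord44_ct": rec.snord44_ct,
                    "unisp6_ct": rec.unisp6_ct,
                    "action": dec.action,
                    "dilution_factor": dec.dilution_factor,
                    "extra_dilution_wells": ";".join(dec.extra_dilution_wells),
                }
            )
        except QCIncompleteError:
            rows.append(
                {
                    "sample_id": rec.sample_id,
                    "snord44_ct": rec.snord44_ct,
                    "unisp6_ct": rec.unisp6_ct,
                    "action": "qc_incomplete",
                    "dilution_factor": None,
                    "extra_dilution_wells": "",
                }
            )
    return pd.DataFrame(rows)
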