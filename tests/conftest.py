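import numpy as np
import pandas as pd
import pytest

from ringtrial.io import ABSOLUTE_UM, CONTROL, NIST, NIST_DILUTION, PTSD, MeasurementTable


def make_rows(
    platform="PlatA",
    shipment=1,
    group=PTSD,
    parent="P01",
    slots=("a", "b"),
    metabolite="Ala",
    values=(100.0, 100.0),
    unit_kind=ABSOLUTE_UM,
    dilution=None,
):
    """Long-format measurement rows for one parent sample's aliquots."""
    rows = []
    for slot, v in zip(slots, values):
        rows.append(
            {
                "platform": platform,
                "shipment": shipment,
                "sample_id": f"S{shipment}-{parent}{slot}" + (f"-{int(dilution*100)}" if dilution else ""),
                "parent_sample_id": parent,
                "replicate_slot": slot,
                "group": group,
                "dilution_fraction": dilution if dilution is not None else np.nan,
                "metabolite": metabolite,
                "value": v,
                "unit_kind": unit_kind,
                "imputed_by_vendor": False,
            }
        )
    return rows


@pytest.fixture
def duplicate_table():
    """Two parent samples with duplicate aliquots in both shipments, one platform."""
    rows = []
    for shipment, (v1, v2) in [(1, ((90.0, 110.0), (100.0, 100.0))), (2, ((120.0, 130.0), (110.0, 95.0)))]:
        for parent, vals in zip(("P01", "P02"), (v1, v2)):
            rows += make_rows(shipment=shipment, parent=parent, values=vals)
    # a control group so group-dependent stages have both biological groups
    for shipment in (1, 2):
        rows += make_rows(shipment=shipment, group=CONTROL, parent="C01", values=(50.0, 50.0))
    return MeasurementTable(pd.DataFrame(rows))


@pytest.fixture
def nist_table():
    """Shipment-1 reference plasma with a full dilution series, two metabolites."""
    rows = []
    for met, conc in (("Ala", 300.0), ("Gly", 240.0)):
        rows += make_rows(group=NIST, parent="NIST", slots=("a", "b"), metabolite=met,
                          values=(conc, conc), dilution=1.0)
        for frac in (0.8, 0.6, 0.4):
            rows += make_rows(group=NIST_DILUTION, parent="NIST", slots=("a",), metabolite=met,
                              values=(conc * frac,), dilution=frac)
    # biological groups so the table is a realistic shipment
    rows += make_rows(group=PTSD, parent="P01", values=(10.0, 10.0))
    rows += make_rows(group=CONTROL, parent="C01", values=(12.0, 12.0))
    return MeasurementTable(pd.DataFrame(rows))
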