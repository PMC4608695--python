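import numpy as np
import pandas as pd
import pytest

from circaqpcr import data_model, synthetic


def make_agg(ct_by_gene: dict, meta: dict | None = None) -> pd.DataFrame:
    """Aggregated-table builder: {gene: {sample_id: mean_ct}} -> frame."""
    rows = []
    for gene, cts in ct_by_gene.items():
        for sid, ct in cts.items():
            m = (meta or {}).get(sid, {})
            rows.append({
                "sample_id": sid, "animal_id": m.get("animal_id", sid),
                "group": m.get("group", "naive"), "zt": m.get("zt", 0.0),
                "plate": "P1", "gene": gene, "ct": float(ct),
                "n_replicates": 3, "replicate_sd": 0.0,
            })
    return pd.DataFrame(rows)


def make_ct_csv(tmp_path, rows, name="ct.csv",
                header="sample_id,animal_id,group,zt,plate,gene,replicate,ct"):
    path = tmp_path / name
    path.write_text(header + "\n" + "\n".join(rows) + "\n")
    return path


@pytest.fixture(scope="session")
def default_panel():
    """One study-default simulated panel (with epileptic groups), seed 11."""
    cfg = synthetic.default_config(seed=11)
    table, truth = synthetic.simulate_panel(cfg)
    return cfg, table, truth


@pytest.fixture(scope="session")
def default_agg(default_panel):
    _, table, _ = default_panel
    agg, _ = data_model.aggregate_replicates(table)
    return agg
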