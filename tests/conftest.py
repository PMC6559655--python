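import numpy as np
import pandas as pd
import pytest

import rarecnv as rc
from rarecnv.io import CALL_COLUMNS


def make_calls(rows):
    """Build a raw-call frame from (sample, chrom, start, end, type, probes, qual, caller)."""
    return pd.DataFrame(rows, columns=CALL_COLUMNS)


def make_samples(n_cases=4, n_controls=6, batch="B1"):
    rows = []
    for i in range(n_cases):
        rows.append((f"case_{i+1:04d}", "case", "CD" if i % 2 == 0 else "UC",
                     batch, 0.99, 0.12, 0.04))
    for i in range(n_controls):
        rows.append((f"ctrl_{i+1:04d}", "control", "none", batch, 0.99, 0.12, 0.04))
    return pd.DataFrame(rows, columns=[
        "sample_id", "cohort", "subtype", "batch", "call_rate", "lrr_sd", "baf_sd"])


@pytest.fixture(scope="session")
def small_study():
    """A reduced synthetic study with planted signals, shared across tests."""
    cfg = rc.SimulationConfig(
        seed=20240, n_cases=60, n_controls=300, n_cd=30,
        n_chromosomes=4, n_genes=120, background_cnv_rate_per_sample=6.0,
        planted_signals=(
            rc.PlantedSignal(None, "deletion", 8, 1),
            rc.PlantedSignal(None, "duplication", 6, 0),
        ))
    return rc.generate_study(cfg)


@pytest.fixture(scope="session")
def small_result(small_study):
    s = small_study
    return rc.run_pipeline(s.samples, s.calls, s.genes, s.centromeres,
                           s.chrom_lengths, s.segdups, s.immunoglobulin)
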