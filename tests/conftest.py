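import numpy as np
import pandas as pd
import pytest

from gendersem.dag import build_default_graph, to_sem_spec
from gendersem.preprocess import build_analysis_table, carry_forward_biennial
from gendersem.sem import factor_scores, fit_sem
from gendersem.simulate import SyntheticConfig, generate_panel
from gendersem.study import adapt_spec_to_columns


@pytest.fixture(scope="session")
def small_panel():
    """A small clean panel with its truth sidecar (shared, read-only)."""
    cfg = SyntheticConfig(n_persons=400, seed=3)
    panel, truth = generate_panel(cfg)
    return panel, truth, cfg


@pytest.fixture(scope="session")
def migraine_fit():
    """A converged main-model fit on a mid-sized synthetic panel, with its
    analysis table, truth sidecar and factor scores (shared, read-only)."""
    cfg = SyntheticConfig(n_persons=5000, seed=1)
    panel, truth = generate_panel(cfg)
    panel = carry_forward_biennial(panel)
    table, report = build_analysis_table(panel, "migraine")
    spec = adapt_spec_to_columns(to_sem_spec(build_default_graph()), "migraine")
    fit = fit_sem(spec, data=table)
    scores = factor_scores(fit, table)
    return {"config": cfg, "truth": truth, "table": table, "report": report,
            "spec": spec, "fit": fit, "scores": scores}
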