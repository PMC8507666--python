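import numpy as np
import pandas as pd
import pytest

from ctcpheno import synthetic
from ctcpheno.core import ExpressionMatrix

#: archetype cell counts for the 500-cell simulations
COUNTS_500 = {
    "epithelial_mid": 60,
    "epithelial_high": 25,
    "stem_cluster": 35,
    "emt": 150,
    "emt_mid": 60,
    "leukocyte": 120,
    "endothelial": 20,
    "mixed_cluster": 30,
}


@pytest.fixture(scope="session")
def default_archetypes():
    return synthetic.default_archetypes()


@pytest.fixture(scope="session")
def cells_500(default_archetypes):
    """500-cell simulation at default noise with true labels."""
    return synthetic.generate_cells(default_archetypes, COUNTS_500, seed=0)


@pytest.fixture(scope="session")
def cells_500_no_dropout():
    arcs = synthetic.default_archetypes(dropout_prob=0.0)
    return synthetic.generate_cells(arcs, COUNTS_500, seed=0)


@pytest.fixture
def tiny_matrix():
    """2 genes x 2 cells with distinctive values."""
    values = pd.DataFrame(
        {"c1": [1.5, 0.0], "c2": [99.0, 9.0]}, index=["EPCAM", "KRT8"]
    )
    return ExpressionMatrix(values)


@pytest.fixture(scope="session")
def cohort_27():
    return synthetic.generate_cohort(synthetic.CohortSpec(n_patients=27,
                                                          seed=0))


def classification_rates(matrix, labels, config=None):
    """QC + phenotyping recovery and contaminant-removal rates."""
    from ctcpheno import phenotyping, qc
    from ctcpheno.config import PipelineConfig

    config = config or PipelineConfig()
    results = qc.run_qc(matrix, config.min_reads, config.positivity_tpm)
    retained_ids = [r.cell_id for r in results if r.retained]
    retained = matrix.subset_cells(retained_ids)
    annotations = phenotyping.annotate_cells(retained, config)

    contaminant = labels.isin(synthetic.CONTAMINANT_ARCHETYPES)
    removed = contaminant & ~labels.index.isin(retained_ids)
    removal_rate = float(removed.sum() / contaminant.sum())

    by_cell = {a.cell_id: a for a in annotations}
    n_ctc = n_ok = 0
    for cell_id, arch in labels.items():
        if arch not in synthetic.CTC_ARCHETYPES:
            continue
        n_ctc += 1
        a = by_cell.get(cell_id)
        if a is None:
            continue
        if (a.epithelial_group == synthetic.EXPECTED_EPITHELIAL_GROUP[arch]
                and a.emt_stem_group
                == synthetic.EXPECTED_EMT_STEM_GROUP[arch]):
            n_ok += 1
    return n_ok / n_ctc, removal_rate
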