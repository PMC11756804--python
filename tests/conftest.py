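import warnings

import pytest

import cernapipe as cp


@pytest.fixture(scope="session")
def dataset():
    """One default synthetic study, shared read-only across tests."""
    return cp.simulate_dataset(seed=11)


@pytest.fixture(scope="session")
def pipeline_result(dataset):
    """The full pipeline run on the shared dataset."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return cp.run_pipeline(
            counts=dataset.counts,
            annotation=dataset.annotation,
            mirdb=dataset.mirdb,
            targetscan=dataset.targetscan,
            miranda=dataset.miranda,
            localization=dataset.localization,
            ppi=dataset.ppi,
            gene_sets=dataset.gene_sets,
            groups=dataset.groups,
        )


def run_on(ds, **config_updates):
    """Run the pipeline on a dataset with optional config overrides."""
    cfg = cp.PipelineConfig(**config_updates) if config_updates else None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return cp.run_pipeline(
            counts=ds.counts,
            annotation=ds.annotation,
            mirdb=ds.mirdb,
            targetscan=ds.targetscan,
            miranda=ds.miranda,
            localization=ds.localization,
            ppi=ds.ppi,
            gene_sets=ds.gene_sets,
            groups=ds.groups,
            config=cfg,
        )


def triplet_sets(ds, result):
    planted = set(ds.truth.triplets)
    found = set(
        map(tuple, result.triplets[["lncrna_id", "mirna_id", "mrna_id"]].itertuples(index=False))
    )
    return planted, found
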