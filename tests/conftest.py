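import numpy as np
import pandas as pd
import pytest

from pulsekin import db_builder, matrix_assembly, peptide_mapping, sim, turnover


def make_precursor_rows(sample, peptide, k, total, times, charge=2, replicate=1):
    """Noiseless precursor rows from the exact channel kinetics."""
    rows = []
    for t in times:
        light, heavy = sim.light_heavy(total, k, t)
        rows.append((sample, replicate, t, peptide, charge, "light", light))
        rows.append((sample, replicate, t, peptide, charge, "heavy", heavy))
    return rows


def precursor_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["sample", "replicate", "time_h", "peptide", "charge", "channel",
                 "intensity"],
    )


@pytest.fixture(scope="session")
def small_sim():
    """A 40-gene two-condition simulation shared across tests."""
    config = sim.SimConfig(n_genes=40, seed=11)
    transcripts, expression, precursors, truth = sim.simulate_dataset(config)
    return {
        "config": config,
        "transcripts": transcripts,
        "expression": expression,
        "precursors": precursors,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def small_pipeline(small_sim):
    """Downstream products (groups, k_loss, joined matrix) of small_sim."""
    included, _ = db_builder.build_filtered_db(
        small_sim["transcripts"], small_sim["expression"]
    )
    pep_map = peptide_mapping.build_peptide_map(included)
    assignments = peptide_mapping.classify_peptides(
        pep_map, small_sim["transcripts"]
    )
    groups = peptide_mapping.assemble_as_groups(
        assignments, small_sim["expression"]
    )
    estimates, exclusions = turnover.fit_kloss_ria_table(small_sim["precursors"])
    agg = turnover.aggregate_kloss(
        estimates, assignments, groups,
        samples=list(small_sim["truth"].samples),
    )
    pep_int = matrix_assembly.peptide_intensity_from_psilac(small_sim["precursors"])
    protein, _ = matrix_assembly.assemble_protein_matrix(pep_int, assignments, groups)
    omics = matrix_assembly.join_omics(
        protein, agg["group"], small_sim["expression"], groups
    )
    return {
        "db": included,
        "assignments": assignments,
        "groups": groups,
        "estimates": estimates,
        "exclusions": exclusions,
        "agg": agg,
        "omics": omics,
    }
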