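"""Shared fixtures: hand-built mini tables and the full synthetic scenario."""

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import darkzones as dz

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")
from darkzones import biogeography, decision_matrix, normalization
from darkzones import reference_criteria, synthetic_data, tables_io

SCENARIO_SEED = 1


def make_table(domain, genera, sample_specs, counts):
    """Build an AbundanceTable from (sample_id, location, condition, replicate)
    tuples and a row-per-genus count matrix."""
    samples = tuple(tables_io.SampleMeta(*spec) for spec in sample_specs)
    df = pd.DataFrame(
        np.asarray(counts, dtype=np.int64),
        index=pd.Index(genera, name="genus"),
        columns=[s.sample_id for s in samples],
    )
    return tables_io.AbundanceTable(domain=domain, counts=df, samples=samples)


@pytest.fixture
def paired_specs():
    """Two locations x two conditions x two replicates."""
    specs = []
    for loc in ("L1", "L2"):
        for cond, letter in (("control", "C"), ("dark_zone", "D")):
            for rep in (1, 2):
                specs.append((f"{loc}{letter}{rep}", loc, cond, rep))
    return specs


@pytest.fixture(scope="session")
def scenario():
    return synthetic_data.make_reference_scenario(SCENARIO_SEED)


@dataclass
class Analysis:
    scenario: synthetic_data.ScenarioData
    tables: dict
    qpcr: object
    samples: tuple
    normalized: dict
    criteria: list
    matrix: decision_matrix.DecisionMatrix
    clone_scores: list
    flip_scores: list
    biogeo: list


@pytest.fixture(scope="session")
def analysis(scenario):
    """Scenario dataset pushed through the whole pipeline, augmented with a
    clone-of-reference location and a condition-swapped (sign-flipped) copy."""
    tables, qpcr, samples = synthetic_data.with_comparison_location(
        scenario.tables, scenario.qpcr, scenario.samples, "Apse", "Clone"
    )
    tables, qpcr, samples = synthetic_data.with_comparison_location(
        tables, qpcr, samples, "Apse", "Flipped", flip_conditions=True
    )
    normalized = {
        d: normalization.normalize_domain(t, seed=SCENARIO_SEED)
        for d, t in tables.items()
    }
    genus_criteria = {
        d: reference_criteria.select_reference_taxa(
            reference_criteria.genus_delta_logs(normalized[d], "Apse")
        )
        for d in ("bacteria", "fungi")
    }
    criteria = reference_criteria.assemble_criteria(
        genus_criteria["bacteria"],
        genus_criteria["fungi"],
        normalized["archaea"],
        qpcr,
        samples,
        "Apse",
    )
    real_locations = [
        loc for loc in scenario.config.locations if loc != "Apse"
    ]
    scores = {
        loc: decision_matrix.score_location(
            criteria, normalized, qpcr, samples, loc, "Apse"
        )
        for loc in real_locations
    }
    matrix = decision_matrix.build_matrix(criteria, scores)
    clone_scores = decision_matrix.score_location(
        criteria, normalized, qpcr, samples, "Clone", "Apse"
    )
    flip_scores = decision_matrix.score_location(
        criteria, normalized, qpcr, samples, "Flipped", "Apse"
    )
    # classify on the un-augmented dataset (the constructed Clone/Flipped
    # locations would otherwise join the subset genera's location sets)
    plain = {
        d: normalization.normalize_domain(t, seed=SCENARIO_SEED)
        for d, t in scenario.tables.items()
        if d in ("bacteria", "fungi")
    }
    biogeo = biogeography.classify_genera([plain["bacteria"], plain["fungi"]])
    return Analysis(
        scenario=scenario,
        tables=tables,
        qpcr=qpcr,
        samples=samples,
        normalized=normalized,
        criteria=criteria,
        matrix=matrix,
        clone_scores=clone_scores,
        flip_scores=flip_scores,
        biogeo=biogeo,
    )
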