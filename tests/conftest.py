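import pytest

import mvctriage as mt


@pytest.fixture(scope="session")
def schema():
    return mt.table1_schema()


@pytest.fixture(scope="session")
def faithful():
    """Fixture-faithful cohort: 11,971 crashes with the embedded joint
    (dispatch code x outcome) counts."""
    return mt.sample_fixture_faithful(seed=11971)


@pytest.fixture(scope="session")
def faithful_run(faithful):
    """All five model families swept on the fixture-faithful cohort."""
    return mt.run_all_families(faithful, mt.ChaidConfig())


def toy_schema():
    """Minimal schema for hand-built tree-growth examples."""
    return [
        mt.VariableSpec("mpds_code", "nominal", ["X1", "X2", "X3"]),
        mt.VariableSpec("a", "nominal", ["a0", "a1", "a2"]),
        mt.VariableSpec("b", "dichotomous", ["b0", "b1"]),
        mt.VariableSpec("speed", "ordinal", ["50", "60", "70"]),
    ]


def make_dataset(schema, rows):
    """rows: (mpds_code, features-dict, label) triples."""
    records = [mt.CrashRecord(code, dict(features), label=label)
               for code, features, label in rows]
    return mt.Dataset(schema, records)


@pytest.fixture(scope="session")
def mpds_planted_spec():
    """Two-level planted tree reaching every model family's variables:
    dispatch code at the root, trapped / vulnerable-road-user beneath."""
    codes = [r.category for r in mt.load_table2_fixture().rows]
    d_codes = [c for c in codes if c.startswith("29D")]
    other = [c for c in codes if not c.startswith("29D")]
    return mt.PlantedTreeSpec("mpds_code", [
        mt.PlantedBranch(d_codes, subtree=mt.PlantedTreeSpec("anyone_trapped", [
            mt.PlantedBranch(["Anyone trapped"], leaf_prob=0.60),
            mt.PlantedBranch(["No one trapped"], leaf_prob=0.25),
        ])),
        mt.PlantedBranch(other, subtree=mt.PlantedTreeSpec("vulnerable_road_user", [
            mt.PlantedBranch(["Vulnerable"], leaf_prob=0.30),
            mt.PlantedBranch(["Motor vehicle occupant"], leaf_prob=0.08),
        ])),
    ])
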