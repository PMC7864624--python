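import numpy as np
import pandas as pd
import pytest

from doubleread import (
    Panel,
    Reading,
    ReaderProfile,
    default_study_profiles,
    generate_panel,
)


@pytest.fixture(scope="session")
def study_profiles():
    return default_study_profiles()


@pytest.fixture(scope="session")
def study_panel(study_profiles):
    """Default 12-reader, 427-case synthetic study panel."""
    return generate_panel(study_profiles, n_cases=427, prevalence=0.5, seed=0)


@pytest.fixture
def mk_reading():
    """Factory for readings; confidence/complexity given as ordinal levels."""

    def make(reader_id, decision, conf=3, compl=2, case_id="c0"):
        return Reading(
            reader_id=reader_id,
            case_id=case_id,
            decision=decision,
            confidence_level=conf,
            complexity_level=compl,
        )

    return make


def build_manual_panel(decisions, gold, conf_levels=None, compl_levels=None,
                       difficulty=None):
    """Assemble a Panel from explicit per-reader decision arrays.

    ``decisions`` maps reader_id -> 0/1 array over cases; confidence and
    complexity default to constant mid-scale levels.
    """
    n = len(gold)
    case_ids = [f"c{i}" for i in range(n)]
    cases = pd.DataFrame(
        {
            "case_id": case_ids,
            "gold": np.asarray(gold, dtype=np.int64),
            "difficulty": difficulty if difficulty is not None else np.full(n, 0.5),
        }
    )
    frames = []
    for rid, dec in decisions.items():
        frames.append(
            pd.DataFrame(
                {
                    "reader_id": rid,
                    "case_id": case_ids,
                    "decision": np.asarray(dec, dtype=np.int64),
                    "confidence_level": (
                        conf_levels[rid] if conf_levels else np.full(n, 3)
                    ),
                    "complexity_level": (
                        compl_levels[rid] if compl_levels else np.full(n, 2)
                    ),
                }
            )
        )
    profiles = {
        rid: ReaderProfile(rid, "human", 0.8, 0.8) for rid in decisions
    }
    return Panel(
        cases=cases, readings=pd.concat(frames, ignore_index=True),
        profiles=profiles,
    ).validate()
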