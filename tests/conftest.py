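import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import symptomics as sy

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def lex():
    return sy.demo_lexicon()


@pytest.fixture(scope="session")
def table1_records():
    """Three short narratives with known filtered symptom sets."""
    return [
        sy.NarrativeRecord(
            "1", "I feel low mood. I don’t like doing anything, just feel lethargic."
        ),
        sy.NarrativeRecord(
            "2",
            "I am always having apprehensions. Often I can’t sleep at night and "
            "the lack of sleep is making it difficult for me to carry out my "
            "jobs. These days, I often feel panic attacks.",
        ),
        sy.NarrativeRecord(
            "3",
            "I used to hear voices, and that used to make me feel anxious all "
            "the time. Often I wouldn’t be able to sleep at night. But then I "
            "started my medications, and it’s much better now.",
        ),
    ]


TABLE1_EXPECTED = {
    "1": {"low mood", "lethargy"},
    "2": {"apprehensions", "lack of sleep", "panic attacks"},
    "3": {"auditory hallucination", "anxiety", "lack of sleep"},
}


def strata_matrix(strata):
    """Binary matrix realising given (n, n_with_index, n_symptoms) strata.

    Index-symptom rows get the index plus k-1 dummy symptoms; the rest get k
    dummies.  Used to reconstruct a dataset from a printed stratified table.
    """
    cols = ["index"] + [f"s{j}" for j in range(4)]
    rows = []
    for n, with_index, k in strata:
        for _ in range(with_index):
            rows.append(["index"] + [f"s{j}" for j in range(k - 1)])
        for _ in range(n - with_index):
            rows.append([f"s{j}" for j in range(k)])
    data = np.zeros((len(rows), len(cols)), dtype=np.int8)
    for i, syms in enumerate(rows):
        for s in syms:
            data[i, cols.index(s)] = 1
    return pd.DataFrame(
        data, index=pd.Index([str(i) for i in range(len(rows))], name="patient_id"),
        columns=cols,
    )


@pytest.fixture(scope="session")
def study_strata_matrix():
    """The published stratified counts realised as an explicit binary matrix."""
    return strata_matrix(
        [(704, 0, 0), (964, 7, 1), (944, 6, 2), (791, 14, 3), (7530, 597, 4)]
    )


@pytest.fixture(scope="session")
def default_run():
    """One full default-profile simulation + extraction + cleaning (seed 1)."""
    config, profile, lexicon = sy.default_profile(seed=1)
    records, truth, manifest = sy.simulate_corpus(config, lexicon, profile)
    sets = sy.extract_corpus(records, lexicon)
    matrix = sy.build_matrix(sets, lexicon)
    cleaned, report = sy.clean_matrix(matrix, lexicon, raw_records=records)
    return {
        "config": config,
        "profile": profile,
        "lexicon": lexicon,
        "records": records,
        "truth": truth,
        "manifest": manifest,
        "matrix": matrix,
        "cleaned": cleaned,
        "report": report,
    }
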