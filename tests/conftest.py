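"""Shared fixtures: a hand-transcribed six-field sample corpus and seeded
synthetic corpora at the scales the evaluation properties are checked at.

The expensive end-to-end holdout run (10 balanced classes x 150 records,
default model settings) is computed once per session and shared by every
test that interrogates its report.
"""

import pytest

from crfmap import (
    Corpus,
    FieldRecord,
    SynthConfig,
    evaluate_holdout,
    generate_corpus,
)

# Six realistic eCRF fields (format-hint post-texts, OID jargon, HTML in two
# prompts) with plausible SDTM targets added by hand.
TABLE1_ROWS = [
    ("DRUG_ADMINISTRATION", "AGT_ACTL_DOSE", "Actual Total Dose", "(ddddd.ddd)", "EXDOSE"),
    ("VITAL_SIGNS", "DIAST_BP_VAL", "Diastolic Blood Pressure Value", "(dddddddd)", "VSORRES"),
    ("RAND", "RNDDAT", "<b>Randomization Date</b>", "(GMT)", "DSSTDTC"),
    ("ELIG", "ELIGBRTHDAT", "Date of Birth:", "(MM/DD/YYYY)", "BRTHDTC"),
    ("DC", "DCSYSBP", "Systolic blood pressure:", "(mmHg)", "VSORRES"),
    ("EXPIRATION", "DEATH_MDY_DT", "<b>Date of Death</b>", "(MMM dd yyyy)", "DTHDTC"),
]


@pytest.fixture
def sample_corpus() -> Corpus:
    return Corpus(
        [
            FieldRecord(form_oid=f, field_oid=fd, pre_text=pre, post_text=post, label=lab)
            for f, fd, pre, post, lab in TABLE1_ROWS
        ],
        source="sample",
    )


@pytest.fixture(scope="session")
def balanced_corpus():
    """10 classes x 150 records, moderate shared vocabulary — the reference
    learnable world for end-to-end checks."""
    return generate_corpus(
        SynthConfig(n_classes=10, support=150, shared_token_fraction=0.3, seed=7)
    )


@pytest.fixture(scope="session")
def balanced_report(balanced_corpus):
    """Default-settings 20% stratified holdout on the balanced corpus."""
    return evaluate_holdout(balanced_corpus.corpus, seed=11)


@pytest.fixture(scope="session")
def small_corpus():
    """5 classes x 30 records — fast world for pipeline-shape tests."""
    return generate_corpus(
        SynthConfig(n_classes=5, support=30, shared_token_fraction=0.3, seed=3)
    )
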