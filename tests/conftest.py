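import pytest

from triagerec import (
    CriticalCombination,
    Question,
    QuestionBank,
    SimConfig,
    TopicHierarchy,
    default_archetypes,
    generate_bank,
    generate_corpus,
)


def make_bank(n_questions=12, combinations=()):
    """Hand-sized bank over a two-level hierarchy; questions alternate
    between two organ systems with two symptom groups each."""
    hierarchy = TopicHierarchy(
        [
            ("circulation", [("onset", []), ("character", [])]),
            ("breathing", [("onset", []), ("character", [])]),
        ]
    )
    leaves = [
        ("circulation", "onset"),
        ("circulation", "character"),
        ("breathing", "onset"),
        ("breathing", "character"),
    ]
    questions = {
        qid: Question(
            id=qid,
            text=f"Does the patient report finding {qid}?",
            topic_path=leaves[qid % len(leaves)],
        )
        for qid in range(n_questions)
    }
    combs = [
        CriticalCombination(id=i, members=frozenset(members), urgency_label="acute")
        for i, members in enumerate(combinations)
    ]
    return QuestionBank(questions=questions, hierarchy=hierarchy, critical_combinations=combs)


@pytest.fixture
def small_bank():
    return make_bank(12, combinations=[{0, 1, 2}, {3, 4}, {0, 5}])


@pytest.fixture(scope="session")
def sim_bank():
    """Mid-sized generated bank shared across training tests."""
    return generate_bank(SimConfig(seed=7, n_questions=80, n_combinations=8))


@pytest.fixture(scope="session")
def sim_corpus(sim_bank):
    config = SimConfig(seed=7, n_questions=80, n_combinations=8, n_calls=400)
    return generate_corpus(sim_bank, default_archetypes(sim_bank, config), config)
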