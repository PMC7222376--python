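import pytest

from wag import (
    AssessmentRecord,
    load_config,
    load_default_config,
)
from wag.schema import default_config_path


@pytest.fixture(scope="session")
def config():
    """The shipped default configuration (health + behavior, adult)."""
    return load_default_config()


@pytest.fixture(scope="session")
def extras_config():
    path = default_config_path().parent / "wag_extras_synthetic.yaml"
    return load_config(path)


# Per question, one representative answer of each color in the default
# config; used to build records with prescribed effective colors.
COLOR_ANSWER = {
    "skin_alterations": {"green": "none", "amber": "scars", "red": "open_wounds"},
    "lameness": {"green": "no_lameness", "amber": "lame", "red": "severely_lame"},
    "illness_signs": {"green": "no_signs", "amber": "other", "red": "diarrhea"},
    "coat_healthy": {"green": "yes", "red": "no"},
    "general_attitude": {"green": "at_ease", "amber": "other", "red": "apathetic"},
    "fear_distress": {"green": "no_signs", "amber": "other", "red": "trembling"},
    "harmful_practices": {"green": "none", "amber": "other", "red": "limb_tethering"},
    "owner_interaction": {
        "green": "relaxed_confident",
        "amber": "cautious_fearful",
        "red": "aggressive",
    },
    "with_other_animals": {
        "green": "yes_physical_contact",
        "amber": "yes_visual_contact",
        "red": "no_contact",
    },
}


def record_with_colors(tree, colors, animal_id="a1", group_attrs=None):
    """Build a record whose four effective colors are the given tuple."""
    answers = {
        qid: {COLOR_ANSWER[qid][color]}
        for qid, color in zip(tree.primary_questions, colors)
    }
    return AssessmentRecord(
        animal_id=animal_id,
        age_class=tree.age_class,
        group_attrs=group_attrs or {},
        answers=answers,
    )


@pytest.fixture(scope="session")
def behavior_tree(config):
    return config.tree("behavior", "adult")


@pytest.fixture(scope="session")
def health_tree(config):
    return config.tree("health", "adult")
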