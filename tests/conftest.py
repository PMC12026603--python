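import pytest
from hypothesis import settings

from flavorscape import SynthConfig, generate_corpus, generate_taxonomy

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def bench():
    """The default planted benchmark: 3 portals x 2000 recipes, signature
    rate 0.6, sweet fraction 0.5, appreciation biases (0, -0.6, +0.6)."""
    cfg = SynthConfig(seed=11)
    corpora, gt_corpus = generate_corpus(cfg)
    tax, gt_tax = generate_taxonomy(cfg)
    return cfg, corpora, tax, gt_corpus.merge(gt_tax)


@pytest.fixture()
def tiny_taxonomy_files(tmp_path):
    """The two-ingredient toy taxonomy: tomato -> {c1, c2}, sugar -> {c2, c3};
    profiles c1 -> {green}, c2 -> {sweet}, c3 -> {caramellic, sweet}."""
    ing = tmp_path / "ingredients.tsv"
    prof = tmp_path / "profiles.tsv"
    ing.write_text(
        "ingredient\tcompound_id\n"
        "tomato\tc1\n"
        "tomato\tc2\n"
        "sugar\tc2\n"
        "sugar\tc3\n"
    )
    prof.write_text(
        "compound_id\tprofile_word\n"
        "c1\tgreen\n"
        "c2\tsweet\n"
        "c3\tcaramellic\n"
        "c3\tsweet\n"
    )
    return ing, prof
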