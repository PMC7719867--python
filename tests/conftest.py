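import hypothesis
import pytest

from domatrix import fixtures

hypothesis.settings.register_profile(
    "deterministic", derandomize=True, max_examples=40, deadline=None
)
hypothesis.settings.load_profile("deterministic")


@pytest.fixture
def demo_manifest(tmp_path):
    """Toxin/sigma demo genomes (TcdA+TcdB, BoNT, RpoD) written as domtblout."""
    return fixtures.write_toxin_demo(tmp_path / "demo")


@pytest.fixture
def small_fixture(tmp_path):
    """A small random fixture: (manifest, truth)."""
    spec = fixtures.FixtureSpec(n_genomes=8, domain_vocab_size=15, seed=11)
    return fixtures.generate_fixture(spec, tmp_path / "fx")
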