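import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).resolve().parent))

from lexcalc import build_lexicon, collapse, load_builtin_inventory
from lexcalc.fixtures import fixture_F1, fixture_F2


@pytest.fixture(scope="session")
def ipa():
    return load_builtin_inventory("en_US-IPA")


@pytest.fixture(scope="session")
def f1_entries():
    return fixture_F1()


@pytest.fixture(scope="session")
def f1_view(f1_entries):
    return collapse(build_lexicon(f1_entries), "orthographic")


@pytest.fixture(scope="session")
def f2_lexicon(ipa):
    return build_lexicon(fixture_F2(), ipa, with_pronunciation=True)


@pytest.fixture(scope="session")
def f2_phonological(f2_lexicon):
    return collapse(f2_lexicon, "phonological")


def write_csv(path, rows):
    """Write a headerless CSV fixture file."""
    import csv

    with open(path, "w", newline="", encoding="utf-8") as fh:
        csv.writer(fh).writerows(rows)
    return path
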