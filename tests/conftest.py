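import random

import pytest
from hypothesis import settings

from prefrp import SequenceRecord, default_scale, load_fixture

settings.register_profile("default", derandomize=True, max_examples=100)
settings.load_profile("default")

#: Class membership written out independently of the package's data file,
#: straight from the published three-way grouping.
HIGH = set("GASPD")
MODERATE = set("TENKCQRV")
WEAK = set("HLMIYFW")
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


def brute_force_composition(sequences):
    """Letter-by-letter tally oracle for class composition."""
    counts = {"high": 0, "moderate": 0, "weak": 0}
    skipped = 0
    for seq in sequences:
        for aa in seq.upper():
            if aa in HIGH:
                counts["high"] += 1
            elif aa in MODERATE:
                counts["moderate"] += 1
            elif aa in WEAK:
                counts["weak"] += 1
            else:
                skipped += 1
    return counts, skipped


def brute_force_segments(series, threshold, min_length):
    """Position-by-position run scan oracle for segment calling."""
    out = []
    i, n = 0, len(series)
    while i < n:
        if series[i] <= threshold:
            j = i
            while j < n and series[j] <= threshold:
                j += 1
            if j - i >= min_length:
                out.append((i + 1, j))  # 1-based inclusive
            i = j
        else:
            i += 1
    return out


def random_sequence(rng: random.Random, length: int, alphabet: str = ALPHABET) -> str:
    return "".join(rng.choice(alphabet) for _ in range(length))


@pytest.fixture(scope="session")
def scale():
    return default_scale()


@pytest.fixture(scope="session")
def crotamine() -> SequenceRecord:
    return load_fixture("crotamine")


@pytest.fixture
def fasta_file(tmp_path):
    def _write(entries, name="input.fasta"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for rid, seq in entries:
                fh.write(f">{rid}\n{seq}\n")
        return path

    return _write
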