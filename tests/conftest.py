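import random

import pytest
from hypothesis import HealthCheck, settings

from filamentid import parse_pattern, tmem106b_record
from filamentid.motif import CANONICAL_RESIDUES

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

COMBINED_PATTERN_TEXT = "N-x-[ST]-x(3)-N-x-[ST]-x(10)-N-x-[ST]-x(16)-N-x-[ST]"

RESIDUES = sorted(CANONICAL_RESIDUES)


@pytest.fixture(scope="session")
def combined_pattern():
    """The four-sequon glycosylation fingerprint with exact spacers."""
    return parse_pattern(COMBINED_PATTERN_TEXT)


@pytest.fixture(scope="session")
def tmem106b():
    return tmem106b_record()


def brute_force_scan(pattern, residues):
    """Independent window-by-window oracle for the scanner.

    Expands the pattern into one allowed-residue set (or None for a
    wildcard position) per sequence position and tests every window
    position by position.  Returns 1-based match start positions.
    """
    per_position = []
    for e in pattern.elements:
        if e.is_class:
            per_position.append(set(e.residues))
        else:
            per_position.extend([None] * e.run_length)
    span = len(per_position)
    starts = []
    for i in range(len(residues) - span + 1):
        ok = True
        for j, allowed in enumerate(per_position):
            if allowed is not None and residues[i + j] not in allowed:
                ok = False
                break
        if ok:
            starts.append(i + 1)
    return starts


def random_pattern(rng: random.Random, alphabet=None, max_elements=6):
    """A random valid pattern over an alphabet subset, as text."""
    alphabet = list(alphabet or RESIDUES)
    tokens = []
    for _ in range(rng.randint(1, max_elements)):
        if rng.random() < 0.4:
            n = rng.randint(1, 4)
            tokens.append("x" if n == 1 else f"x({n})")
        else:
            k = rng.randint(1, min(3, len(alphabet)))
            letters = rng.sample(alphabet, k)
            tokens.append(letters[0] if k == 1 else "[" + "".join(letters) + "]")
    return "-".join(tokens)


def random_sequence(rng: random.Random, length, alphabet=None):
    alphabet = alphabet or RESIDUES
    return "".join(rng.choice(alphabet) for _ in range(length))
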