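import numpy as np
import pytest

from crispramp.seqcore import EFFECTOR_PRESETS, NucSequence


@pytest.fixture
def cas12a():
    return EFFECTOR_PRESETS["AsCas12a"]


@pytest.fixture
def cas9():
    return EFFECTOR_PRESETS["SpCas9"]


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), n))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


# ---------------------------------------------------------------------------
# Independent oracles.  These deliberately re-derive results with the most
# naive method possible and share no code with the implementation under test.
# ---------------------------------------------------------------------------

ORACLE_IUPAC = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"}, "B": {"C", "G", "T"},
    "D": {"A", "G", "T"}, "H": {"A", "C", "T"}, "V": {"A", "C", "G"},
    "N": {"A", "C", "G", "T"},
}

_ORC_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def oracle_revcomp(s: str) -> str:
    return "".join(_ORC_COMP[b] for b in reversed(s.upper()))


def oracle_pam_ok(pattern: str, seq: str) -> bool:
    return len(pattern) == len(seq) and all(
        b in ORACLE_IUPAC[p] and b != "N" for p, b in zip(pattern, seq)
    )


def oracle_scan_windows(ref: NucSequence, effector, guide=None, max_mm=None,
                        require_pam=True):
    """Naive window-by-window scan on both strands.

    Yields (start, strand, pam, protospacer, mismatch_offsets).  When guide is
    None every PAM-matching window is yielded (find_pam_sites oracle);
    otherwise windows within the mismatch budget are yielded (search oracle).
    """
    L, p = effector.spacer_len, len(effector.pam)
    n = len(ref.seq)
    out = []
    for strand in "+-":
        seq = ref.seq if strand == "+" else oracle_revcomp(ref.seq)
        for i in range(n - L - p + 1):
            if effector.pam_side == "five_prime":
                pam, proto = seq[i : i + p], seq[i + p : i + p + L]
                lo = i + p
            else:
                proto, pam = seq[i : i + L], seq[i + L : i + L + p]
                lo = i
            if require_pam and not oracle_pam_ok(effector.pam, pam):
                continue
            start = lo if strand == "+" else n - lo - L
            if guide is None:
                out.append((start, strand, pam, proto, ()))
            else:
                mm = tuple(k for k, (a, b) in enumerate(zip(proto, guide)) if a != b)
                if len(mm) <= max_mm:
                    out.append((start, strand, pam, proto, mm))
    return out
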