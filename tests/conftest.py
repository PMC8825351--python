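import numpy as np
import pytest

from rmtcr import synthetic as sy
from rmtcr import vdj_reference as vr


@pytest.fixture(scope="session")
def cregions() -> vr.ReferenceSet:
    """The bundled rhesus TRAC/TRBC constant-region alleles."""
    return vr.load_bundled_cregions()


@pytest.fixture(scope="session")
def small_sim():
    """One deterministic small MLR simulation shared across tests."""
    cfg = sy.SimConfig(seed=7, n_clones=500, n_cells=1000, allo_fraction=0.02)
    rep = sy.sample_repertoire(cfg)
    sim = sy.simulate_mlr(rep, cfg)
    return cfg, rep, sim


def brute_force_stop_scan(seq: str, frame: int) -> list[int]:
    """Independent codon-walk: 0-based positions of in-frame stop codons,
    excluding a terminal stop when the sequence ends in-frame."""
    stops = {"TAA", "TAG", "TGA"}
    hits = [i for i in range(frame, len(seq) - 2, 3) if seq[i : i + 3] in stops]
    if hits and (len(seq) - frame) % 3 == 0 and hits[-1] == len(seq) - 3:
        hits = hits[:-1]
    return hits


def brute_force_primer_scan(template: str, probe: str, max_mm: int) -> list[tuple[int, int]]:
    """Naive O(n*m) sliding-window Hamming scan: (start, mismatches)."""
    out = []
    for s in range(len(template) - len(probe) + 1):
        mm = sum(a != b for a, b in zip(template[s : s + len(probe)], probe))
        if mm <= max_mm:
            out.append((s, mm))
    return out


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))
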