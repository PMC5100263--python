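"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the implementation's code paths
(regexes, interval trees, run extraction): they test every window / pair /
column directly so scanner and extractor outputs can be checked against
first principles.
"""

from __future__ import annotations

from pathlib import Path

import pytest

from regscreen.motif_scan import IUPAC_CLASSES, MotifGrammar
from regscreen.sequence_io import AlignmentBlock

# ---------------------------------------------------------------------------
# Brute-force motif oracles
# ---------------------------------------------------------------------------

def window_matches(window: str, pattern: str) -> bool:
    """Direct per-symbol degeneracy-class check of one window."""
    if len(window) != len(pattern):
        return False
    return all(base in IUPAC_CLASSES[sym] for base, sym in zip(window, pattern))


def brute_monomers(text: str, grammar: MotifGrammar,
                   strand_mode: str = "both") -> list[tuple[int, str]]:
    """Every (start, strand) where a length-k window matches a pattern set."""
    k = grammar.monomer_length
    out = []
    for i in range(len(text) - k + 1):
        w = text[i:i + k]
        if any(window_matches(w, p) for p in grammar.forward_patterns):
            out.append((i, "+"))
        if strand_mode == "both" and any(
                window_matches(w, p) for p in grammar.reverse_patterns):
            out.append((i, "-"))
    return sorted(out)


def brute_dimers(text: str, grammar: MotifGrammar
                 ) -> list[tuple[int, int, int]]:
    """Every (fwd_start, spacer_len, rev_start) triple, tested directly."""
    k = grammar.monomer_length
    out = []
    for i in range(len(text) - k + 1):
        if not any(window_matches(text[i:i + k], p)
                   for p in grammar.forward_patterns):
            continue
        for spacer in range(grammar.spacer_min, grammar.spacer_max + 1):
            j = i + k + spacer
            if j + k > len(text):
                break
            if any(window_matches(text[j:j + k], p)
                   for p in grammar.reverse_patterns):
                out.append((i, spacer, j))
    return out


# ---------------------------------------------------------------------------
# Brute-force conservation oracle
# ---------------------------------------------------------------------------

def brute_identical_segments(blocks, species: tuple[str, ...],
                             reference: str, min_length: int
                             ) -> list[tuple[str, int, int]]:
    """Label each column, extract maximal runs — no shared code with the
    implementation's incremental scan."""
    segments = []
    for block in blocks:
        rows = {r.species: r for r in block.rows}
        if reference not in rows:
            raise ValueError("reference absent")
        if any(sp not in rows for sp in species):
            continue
        ref = rows[reference]
        width = len(ref.text)
        # reference coordinate of each column (None on reference gaps)
        ref_coord = []
        pos = ref.start
        for c in ref.text:
            if c == "-":
                ref_coord.append(None)
            else:
                ref_coord.append(pos)
                pos += 1
        good = []
        for col in range(width):
            chars = {rows[sp].text[col].upper() for sp in species}
            good.append(len(chars) == 1 and chars <= set("ACGT")
                        and ref_coord[col] is not None)
        col = 0
        while col < width:
            if good[col]:
                start = col
                while col < width and good[col]:
                    col += 1
                length = col - start
                if length >= min_length:
                    segments.append((ref.chrom or ref.species,
                                     ref_coord[start],
                                     ref_coord[col - 1] + 1))
            else:
                col += 1
    return sorted(segments)


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def default_grammar() -> MotifGrammar:
    return MotifGrammar()


@pytest.fixture(scope="session")
def bundle_dir(tmp_path_factory) -> Path:
    """One synthetic input bundle shared across tests that only read it."""
    from regscreen.synthetic_data import SimulationConfig, simulate_bundle

    outdir = tmp_path_factory.mktemp("bundle")
    simulate_bundle(SimulationConfig(seed=11), outdir)
    return outdir


def random_sequence(rng, length: int, p=(0.295, 0.205, 0.205, 0.295)) -> str:
    import numpy as np

    return "".join(rng.choice(np.array(list("ACGT")), size=length, p=list(p)))
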