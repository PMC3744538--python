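"""Shared fixtures and independent oracles for the test suite."""

import math

import pytest

import poloscan as ps


@pytest.fixture(scope="session")
def kinase():
    return ps.compile_motif(ps.KINASE_CONSENSUS, name="kinase")


@pytest.fixture(scope="session")
def pbd():
    return ps.compile_motif(ps.PBD_CONSENSUS, name="pbd")


@pytest.fixture(scope="session")
def default_world():
    """The default synthetic world at seed 7 plus a full screen run."""
    spec = ps.SyntheticSpec(seed=7)
    records, annotations, truth = ps.generate_world(spec)
    result = ps.run_screen(records, annotations, ps.PipelineConfig())
    return spec, records, annotations, truth, result


def naive_scan(seq, motif, min_similarity):
    """Per-window reference scanner, independent of the library's path.

    Tests every window position set by set; returns (start, window,
    similarity, phospho_position, per_position_match) tuples for windows
    whose phosphoacceptor matches exactly and whose similarity reaches
    the threshold.
    """
    ell = motif.length
    needed = math.ceil(min_similarity * ell - 1e-9)
    out = []
    for s in range(len(seq) - ell + 1):
        window = seq[s : s + ell]
        matches = []
        for i, allowed in enumerate(motif.positions):
            if allowed == ps.FULL_ALPHABET:
                matches.append(True)
            else:
                matches.append(window[i] in allowed)
        acceptor = window[motif.phospho_index - 1]
        if acceptor not in motif.positions[motif.phospho_index - 1]:
            continue
        if sum(matches) < needed:
            continue
        out.append(
            (
                s + 1,
                window,
                sum(matches) / ell,
                s + motif.phospho_index,
                tuple(matches),
            )
        )
    return out


def hits_as_tuples(hits):
    return [
        (h.start, h.window, h.similarity, h.phospho_position, h.per_position_match)
        for h in hits
    ]
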