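"""Shared helper: probe set with injected sequence biases for QC recovery tests."""

import numpy as np

from chiptile.datamodel import ProbeSet
from chiptile.qc import gc_content


def build_bias_fixture(n=10_000, L=25, seed=42):
    """Random probes plus two intensity vectors: one with a linear GC slope,
    one with a +delta effect for base G at position 13."""
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    seqs = ["".join(bases[rng.integers(0, 4, L)]) for _ in range(n)]
    probes = ProbeSet(
        probe_ids=[f"p{i}" for i in range(n)],
        sequences=seqs,
        array_x=np.arange(n) % 200,
        array_y=np.arange(n) // 200,
    )
    alpha, beta = 2.0, 0.1
    gc = np.array([gc_content(s) for s in seqs])
    vals_gc = alpha + beta * gc + rng.normal(0, 0.01, size=n)
    delta = 0.5
    hits = np.array([s[13] == "G" for s in seqs])
    vals_pos = 1.0 + delta * hits + rng.normal(0, 0.1, size=n)
    return probes, vals_gc, vals_pos, delta, alpha, beta
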