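"""Shared toy-object builders for the test suite."""

import numpy as np

from splicestr.splicing import SpliceEvent


def make_toy_event(event_id="toy", psi_zero_frac=0.0, n=100):
    psi = np.linspace(5, 95, n)
    n_zero = int(round(psi_zero_frac * n))
    if n_zero:
        psi[:n_zero] = 0.0
    return SpliceEvent(
        id=event_id, event_type="SE", gene="g", chrom="chrT", strand="+",
        constitutive_exons=[(1_000, 1_100), (9_000, 9_100)],
        target_exons=[(5_000, 5_100)],
        psi=psi, read_counts=np.full(n, 50.0))
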