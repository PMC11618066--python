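"""Small worked-example tables used by the test suite and documentation.

Two tallies are encoded exactly:

* a human-style snRNA call table in which 28 cells are double-positive for
  Lepr and Bnc2 and 23 of those carry none of Agrp/Npy/Pomc (a 82.1%
  triple-negative fraction);
* an optogenetic circuit-mapping tally in which 25 of 31 recorded neurons
  show a light-evoked inhibitory current (an ~81% responder rate).

Both tables are synthetic stand-ins generated from a seed; the marginal
tallies, not the individual rows, are the meaningful quantities.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

FIXTURE_GENES = ("Lepr", "Bnc2", "Agrp", "Npy", "Pomc")


def human_call_counts(seed: int = 0, n_extra: int = 12) -> pd.DataFrame:
    """Synthetic per-cell UMI counts reproducing the 23-of-28 tally.

    Exactly 28 cells have >= 2 UMIs for both Lepr and Bnc2; 23 of them have
    <= 1 UMI for each of Agrp/Npy/Pomc and 5 have >= 2 for at least one.
    ``n_extra`` additional cells are not double-positive.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(28):
        marker_counts = [0, 0, 0]
        if i >= 23:  # the 5 marker-positive double-positives
            marker_counts[int(rng.integers(3))] = int(rng.integers(2, 6))
        rows.append([int(rng.integers(2, 8)), int(rng.integers(2, 8)), *marker_counts])
    for _ in range(n_extra):  # not Lepr+/Bnc2+ double-positive
        which = int(rng.integers(3))
        lepr = int(rng.integers(2, 6)) if which == 0 else int(rng.integers(0, 2))
        bnc2 = int(rng.integers(2, 6)) if which == 1 else int(rng.integers(0, 2))
        rows.append([lepr, bnc2, int(rng.integers(0, 2)), 0, 0])
    df = pd.DataFrame(rows, columns=list(FIXTURE_GENES))
    df.index = [f"hCELL{i:03d}" for i in range(len(df))]
    df.index.name = "cell"
    return df


def oipsc_responder_tally(seed: int = 0) -> pd.DataFrame:
    """31 recorded neurons, 25 of them light-evoked-current responders."""
    rng = np.random.default_rng(seed)
    responder = np.zeros(31, dtype=bool)
    responder[rng.permutation(31)[:25]] = True
    return pd.DataFrame(
        {"cell": [f"rec{i:02d}" for i in range(31)], "responder": responder}
    ).set_index("cell")


def responder_percent(tally: pd.DataFrame) -> float:
    """Percent of recorded neurons flagged as responders."""
    return 100.0 * float(tally["responder"].mean())


def make_fixtures(seed: int = 0, outdir: str | Path | None = None) -> dict[str, pd.DataFrame]:
    """Build (and optionally write as TSV) the worked-example tables."""
    bundle = {
        "human_calls": human_call_counts(seed),
        "oipsc_responders": oipsc_responder_tally(seed),
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in bundle.items():
            df.to_csv(outdir / f"{name}.tsv", sep="\t")
    return bundle
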