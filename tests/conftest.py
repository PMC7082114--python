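import numpy as np
import pandas as pd
import pytest

from chemoscreen.core_io import ExpressionMatrix, ScreenCounts, SgRNALibrary


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def tiny_library():
    genes = [f"g{i}" for i in range(5)]
    entries = pd.DataFrame(
        {
            "sgrna_id": [f"g{i}_sg{j}" for i in range(5) for j in range(4)],
            "gene_id": np.repeat(genes, 4),
        }
    )
    return SgRNALibrary(entries=entries)


@pytest.fixture
def tiny_screen(tiny_library, rng):
    sgrnas = list(tiny_library.entries["sgrna_id"])
    cols = {"plasmid": rng.integers(50, 500, len(sgrnas))}
    meta = [("plasmid", "pool", "plasmid", 0)]
    for line in ("A", "B"):
        for arm in ("dmso", "treated"):
            name = f"{line}_{arm}"
            cols[name] = rng.integers(20, 600, len(sgrnas))
            meta.append((name, line, arm, 14))
    counts = pd.DataFrame(cols, index=sgrnas)
    meta = pd.DataFrame(meta, columns=["sample", "cell_line", "arm", "day"]).set_index("sample")
    return ScreenCounts(counts=counts, meta=meta, library=tiny_library)


@pytest.fixture
def tiny_panel(rng):
    genes = [f"g{i}" for i in range(40)]
    lines = [f"s{i}" for i in range(2)] + [f"i{i}" for i in range(2)]
    cols, meta = {}, []
    for ln in lines:
        group = "sensitive" if ln.startswith("s") else "insensitive"
        for tr in ("dmso", "treated"):
            name = f"{ln}_{tr}"
            cols[name] = rng.integers(5, 800, len(genes))
            meta.append((name, ln, group, tr, 1))
    counts = pd.DataFrame(cols, index=genes)
    meta = pd.DataFrame(
        meta, columns=["sample", "cell_line", "group", "treatment", "replicate"]
    ).set_index("sample")
    return ExpressionMatrix(counts=counts, meta=meta)
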