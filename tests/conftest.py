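import numpy as np
import pandas as pd
import pytest

from epidrugscreen import synthetic as syn


@pytest.fixture
def tiny_screen_truth():
    """Two lines, three compounds covering all kinetics, noise-free."""
    lines = ["L1", "L2"]
    compounds = [("DLY", "A"), ("ACU", "B"), ("NIL", "C")]
    fourpl = {
        (line, comp): (1.0, 0.0, 1e-6, 1.0) for line in lines for comp, _ in compounds
    }
    kinetics = {"DLY": "delayed", "ACU": "acute", "NIL": "inert"}
    return syn.ScreenTruth(
        lines=lines,
        compounds=compounds,
        fourpl=fourpl,
        kinetics=kinetics,
        noise_sd=0.0,
        kinetic_ic50_factor=10.0,
    )


@pytest.fixture
def small_bundle():
    """Small expression bundle: 6 lines x 3 compounds, near-noiseless."""
    truth = syn.expression_truth(
        lines=[f"L{i}" for i in range(1, 7)],
        compounds=["D1", "D2", "D3"],
        n_genes=300,
        seed=11,
        module_sizes=(),
        consistent_down_compound="D1",
        consistent_down_size=20,
        n_cluster_markers=10,
        stress_set_size=5,
        specific_up_size=10,
        specific_down_size=10,
        cluster2_lines={"L5", "L6"},
    )
    bundle = syn.generate_expression(
        truth,
        [f"L{i}" for i in range(1, 7)],
        ["D1", "D2", "D3"],
        dispersion=1e-4,
        seed=12,
        extra_log2_sd=0.0,
        equal_libsize=True,
    )
    return truth, bundle


def make_grid(up_cells=None, down_cells=None, lines=None, compounds=None):
    """Build a GeneSetGrid from sparse {(line, compound): iterable} dicts."""
    from epidrugscreen.overlap import GeneSetGrid

    up_cells = {k: set(v) for k, v in (up_cells or {}).items()}
    down_cells = {k: set(v) for k, v in (down_cells or {}).items()}
    keys = set(up_cells) | set(down_cells)
    lines = lines or sorted({k[0] for k in keys})
    compounds = compounds or sorted({k[1] for k in keys})
    for line in lines:
        for comp in compounds:
            up_cells.setdefault((line, comp), set())
            down_cells.setdefault((line, comp), set())
    return GeneSetGrid(
        up_sets=up_cells, down_sets=down_cells, lines=lines, compounds=compounds
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def random_peaks(rng):
    def make(n, genome=1_000_000, seed=None):
        r = np.random.default_rng(seed) if seed is not None else rng
        starts = r.choice(genome, size=n, replace=False)
        widths = r.integers(100, 900, size=n)
        return pd.DataFrame(
            {
                "chrom": "chr1",
                "start": starts,
                "end": starts + widths,
                "score": r.lognormal(3.0, 0.4, size=n),
            }
        )

    return make
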