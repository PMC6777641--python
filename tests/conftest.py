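import io

import pytest

from amquant.datasets import (EXAMPLE_GRID_CSV, EXAMPLE_TROUVELOT_CSV,
                              load_example_grid, load_example_trouvelot)


@pytest.fixture(scope="session")
def grid_csv_text():
    return EXAMPLE_GRID_CSV


@pytest.fixture(scope="session")
def trouvelot_csv_text():
    return EXAMPLE_TROUVELOT_CSV


@pytest.fixture()
def grid_ds():
    return load_example_grid()


@pytest.fixture()
def trouvelot_ds():
    return load_example_trouvelot()


@pytest.fixture()
def grid_total_groups(grid_ds):
    """The Total column split by sample, in sample order."""
    frame = grid_ds.to_frame()
    return [frame.loc[frame["Samples"] == s, "Total"].to_numpy(dtype=float)
            for s in grid_ds.sample_order]


def stream(text: str) -> io.StringIO:
    return io.StringIO(text)
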