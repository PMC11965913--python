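import pandas as pd
import pytest

import phenostat as ps


@pytest.fixture(scope="session")
def fixture_spec() -> ps.DesignSpec:
    """Default-design fixture with a small planted-outlier fraction."""
    return ps.DesignSpec(seed=11, outlier_rate=0.02)


@pytest.fixture(scope="session")
def fixture_project(tmp_path_factory, fixture_spec):
    """A generated project directory: archive, annotations, groups, design."""
    outdir = tmp_path_factory.mktemp("fixture_project")
    paths, truth = ps.generate_experiment(fixture_spec, outdir)
    return outdir, paths, truth


@pytest.fixture(scope="session")
def prepared_project(fixture_project):
    """The fixture project after the full prepare stage."""
    outdir, paths, truth = fixture_project
    table, report = ps.prepare_project(outdir)
    return outdir, table, report, truth


def gap_split_labels(timestamps, eps_hours: float):
    """Independent oracle: sort timestamps and split wherever the gap to the
    previous one exceeds eps.  Equivalent to DBSCAN with min_pts=1 in 1-D."""
    ts = pd.to_datetime(pd.Series(list(timestamps)))
    order = ts.sort_values(kind="stable").index
    labels = {}
    current = -1
    prev = None
    for idx in order:
        t = ts[idx]
        if prev is None or (t - prev).total_seconds() > eps_hours * 3600.0:
            current += 1
        labels[idx] = current
        prev = t
    return [labels[i] for i in ts.index]
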