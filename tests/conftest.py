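import textwrap

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


EVENT_HEADER = (
    "timestamp,site_id,box_id,night_id,individual_id,event_type,"
    "door_id,latch_type,work_time_s,exploratory_diversity"
)


@pytest.fixture
def write_events(tmp_path):
    """Write an events CSV from compact row strings and return its path."""

    def _write(rows: list[str], name: str = "events.csv"):
        path = tmp_path / name
        path.write_text(EVENT_HEADER + "\n" + "\n".join(rows) + "\n")
        return path

    return _write


@pytest.fixture
def simple_roster(tmp_path):
    path = tmp_path / "individuals.csv"
    path.write_text(
        textwrap.dedent(
            """\
            individual_id,sex,age,first_test_year
            A,female,adult,2016
            B,male,juvenile,2016
            C,female,adult,2016
            """
        )
    )
    return path
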