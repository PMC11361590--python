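import pytest

from tileforge.annotation_io import AnnotatedRegion, AnnotationSet
from tileforge.synthetic import (
    generate_fixture,
    make_basic_case,
    make_checkerboard_case,
    make_concave_case,
    make_offset_grid_case,
)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    return tmp_path_factory.mktemp("fixtures")


@pytest.fixture(scope="session")
def basic_fixture(fixture_dir):
    return generate_fixture(make_basic_case(), str(fixture_dir / "basic"))


@pytest.fixture(scope="session")
def offset_fixture(fixture_dir):
    return generate_fixture(make_offset_grid_case(), str(fixture_dir / "offset"))


@pytest.fixture(scope="session")
def checkerboard_fixture(fixture_dir):
    return generate_fixture(make_checkerboard_case(), str(fixture_dir / "checker"))


@pytest.fixture(scope="session")
def concave_fixture(fixture_dir):
    spec, probe_tile = make_concave_case()
    result = generate_fixture(spec, str(fixture_dir / "concave"))
    return result, probe_tile


def square_region(x0, y0, x1, y1, label="tumor", region_id="sq"):
    return AnnotatedRegion(
        label=label,
        exterior=[(x0, y0), (x1, y0), (x1, y1), (x0, y1)],
        region_id=region_id,
    )


@pytest.fixture
def square_annotation():
    return AnnotationSet("slide", [square_region(0, 0, 1024, 1024)])
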