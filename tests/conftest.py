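import pytest

import admetprof as ap


@pytest.fixture(scope="session")
def registry():
    return ap.RangeRegistry.default()


@pytest.fixture(scope="session")
def filters():
    return ap.load_filters()


@pytest.fixture(scope="session")
def toy_records():
    return ap.toy_library()


@pytest.fixture(scope="session")
def toy_records_3d():
    return ap.toy_library(embed_3d=True)


def by_id(records, cid):
    return next(r for r in records if r.id == cid)
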