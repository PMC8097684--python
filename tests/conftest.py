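import io

import pytest

from virdb.query import FixtureFetcher, QueryFlags
from virdb.records import parse_input_spec
from virdb.simulate import mock_community
from virdb.versioning import build_database


@pytest.fixture(scope="session")
def community():
    return mock_community(seed=0)


@pytest.fixture(scope="session")
def archive_fetcher(community):
    return FixtureFetcher(
        community.all_genbank_entries(), taxid_children=community.taxid_children
    )


@pytest.fixture
def built_db(tmp_path, community, archive_fetcher):
    """A freshly downloaded mock-community database directory."""
    specs = parse_input_spec(io.StringIO(community.input_spec_text()))
    db_dir = tmp_path / "db"
    manifest = build_database(
        db_dir, specs, archive_fetcher, flags=QueryFlags(exclude_human=True)
    )
    return db_dir, manifest, specs
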