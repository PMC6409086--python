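import os

import pytest
from hypothesis import HealthCheck, settings

# The autouse config-isolation fixture is function-scoped but stateless
# across hypothesis examples, so the corresponding health check is noise.
settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.function_scoped_fixture],
)
settings.load_profile("suite")


@pytest.fixture(autouse=True)
def isolated_config(tmp_path, monkeypatch):
    """Keep every test away from the user's real config and cache."""
    monkeypatch.setenv("DATATOTE_CONFIG", str(tmp_path / "no-such-config.json"))
    cache = tmp_path / "cache"
    monkeypatch.setenv("DATATOTE_CACHE_DIRECTORY", str(cache))
    monkeypatch.setenv("DATATOTE_USERNAME", "testuser")
    return cache


@pytest.fixture(params=["file", "mock"], ids=["disk-broker", "mock-object-broker"])
def base_uri(request, tmp_path):
    """A writable base URI, once per concrete storage broker.

    Every test using this fixture runs against both brokers, which is how
    the suite demonstrates that datasets behave identically whatever the
    storage medium.
    """
    base = tmp_path / "base-{}".format(request.param)
    base.mkdir()
    return "{}://{}".format(request.param, base)


@pytest.fixture
def disk_base(tmp_path):
    base = tmp_path / "disk-base"
    base.mkdir()
    return str(base)


@pytest.fixture
def mock_base(tmp_path):
    base = tmp_path / "mock-base"
    base.mkdir()
    return "mock://{}".format(base)


@pytest.fixture
def make_file(tmp_path):
    """Write bytes to a scratch file and return its path."""
    scratch = tmp_path / "sources"
    scratch.mkdir(exist_ok=True)
    counter = {"n": 0}

    def _make(content: bytes, name: str | None = None, mtime: float | None = None):
        counter["n"] += 1
        path = scratch / (name or "src-{}".format(counter["n"]))
        path.write_bytes(content)
        if mtime is not None:
            os.utime(path, (mtime, mtime))
        return str(path)

    return _make
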