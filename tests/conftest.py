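import pytest

from oceanpack import (
    LoadedPackage,
    default_unit_registry,
    generate_package,
    load_default_terms,
)


@pytest.fixture(scope="session")
def graph():
    return load_default_terms()


@pytest.fixture(scope="session")
def registry():
    return default_unit_registry()


@pytest.fixture
def clean_package(tmp_path):
    """A freshly generated defect-free package on disk."""
    pkg_dir = tmp_path / "pkg"
    pkg, manifest = generate_package(pkg_dir, n_samples=12, seed=5)
    return pkg, manifest, pkg_dir


@pytest.fixture
def loaded_clean_package(clean_package):
    _, manifest, pkg_dir = clean_package
    return LoadedPackage.from_dir(pkg_dir), manifest
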