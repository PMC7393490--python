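import pathlib

import pytest

from somaticmerge.callers import CallerId, read_caller_vcf
from somaticmerge.simulate import DEFAULT_PROFILES, TruthSpec, simulate_dataset


@pytest.fixture(scope="session")
def dataset(tmp_path_factory):
    """A small simulated seven-caller dataset shared across tests."""
    out = tmp_path_factory.mktemp("dataset")
    spec = TruthSpec(contig_length=50_000, n_snv=120, n_indel=25, seed=7)
    return simulate_dataset(out, spec, [DEFAULT_PROFILES[c] for c in CallerId])


@pytest.fixture(scope="session")
def callsets(dataset):
    """The dataset read back through the dialect readers, per caller."""
    return {
        caller: read_caller_vcf(calls.path, caller, reference=dataset.reference_path)
        for caller, calls in dataset.calls.items()
    }


def write_vcf(path: pathlib.Path, header_lines: list[str], body_lines: list[str]) -> pathlib.Path:
    """Write a minimal VCF from explicit header/body lines."""
    lines = ["##fileformat=VCFv4.2", *header_lines, *body_lines]
    path.write_text("\n".join(lines) + "\n")
    return path
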