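import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def write_fasta(tmp_path):
    def _write(seq, name="g", filename="genome.fa"):
        path = tmp_path / filename
        path.write_text(f">{name}\n{seq}\n")
        return str(path)
    return _write


@pytest.fixture()
def write_gff(tmp_path):
    def _write(rows, filename="ann.gff3", seqid="g"):
        lines = ["##gff-version 3"]
        for i, (start1, end1, strand, ftype) in enumerate(rows):
            lines.append(
                f"{seqid}\ttest\t{ftype}\t{start1}\t{end1}\t.\t{strand}\t0\t"
                f"ID=G{i:03d};locus_tag=G{i:03d}"
            )
        path = tmp_path / filename
        path.write_text("\n".join(lines) + "\n")
        return str(path)
    return _write
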