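"""Builder for the packaged noise-free golden-run fixture.

The golden report (tests/data/golden_report.json) is the byte-for-byte
output of this run; regenerate it after an intentional behaviour change
with, from the repository root:

    python -c "import sys; sys.path.insert(0, 'tests'); \
               from golden_fixture import regenerate; regenerate()"
"""

from __future__ import annotations

import os
from pathlib import Path

import alsact as A
from alsact import io as aio

GOLDEN_PATH = Path(__file__).parent / "data" / "golden_report.json"


def run_golden_pipeline(workdir: Path) -> bytes:
    """Run the full file pipeline on the fixed noise-free fixture inside
    ``workdir`` (paths in the config are relative, so the config hash and
    the report are location-independent) and return report.json bytes."""
    cfg = A.CohortConfig(
        n_persons=60, seed=7, noise=A.NoiseConfig.zero(),
    )
    cohort = A.generate_cohort(cfg)
    register = A.generate_register(A.RegisterConfig.uk_like(seed=7))
    uk = A.load_uk_incidence()
    register = register.merge(
        uk[["age_group", "sex", "standard_pop"]], on=["age_group", "sex"]
    )
    workdir.mkdir(parents=True, exist_ok=True)
    cwd = os.getcwd()
    os.chdir(workdir)
    try:
        aio.write_variant_table(cohort.variants, "variants.tsv")
        aio.write_tsv(cohort.metrics, "sample_metrics.tsv")
        aio.write_tsv(cohort.repeats, "repeat_calls.tsv")
        aio.write_tsv(register, "register.tsv")
        run = A.RunConfig(
            variants="variants.tsv",
            metrics="sample_metrics.tsv",
            repeats="repeat_calls.tsv",
            register="register.tsv",
            out_dir="out",
            seed=7,
        )
        A.run_pipeline(run)
        return (Path("out") / "report.json").read_bytes()
    finally:
        os.chdir(cwd)


def regenerate() -> None:
    import tempfile

    with tempfile.TemporaryDirectory() as tmp:
        payload = run_golden_pipeline(Path(tmp))
    GOLDEN_PATH.parent.mkdir(parents=True, exist_ok=True)
    GOLDEN_PATH.write_bytes(payload)
    print(f"wrote {GOLDEN_PATH} ({len(payload)} bytes)")
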