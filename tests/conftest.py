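import pytest

import plasenrich as pe


def make_record(
    read_id="r1",
    channel=1,
    region=pe.Region.AS,
    start_time=0.0,
    duration=1.0,
    length=1000,
    barcode="RBK01",
    replicon_class=pe.RepliconClass.UNMAPPED,
    sample=None,
    rejected=False,
):
    return pe.ReadRecord(
        read_id=read_id,
        channel=channel,
        region=region,
        start_time=start_time,
        duration=duration,
        length=length,
        barcode=barcode,
        replicon_class=replicon_class,
        sample=sample,
        rejected=rejected,
    )


@pytest.fixture
def toy_table():
    return pe.RepliconTable(
        {
            "sampleA_chromosome": pe.Replicon("sampleA", pe.RepliconClass.CHROMOSOME, 5000),
            "sampleA_plasmid1": pe.Replicon("sampleA", pe.RepliconClass.PLASMID, 1000),
            "sampleB_chromosome": pe.Replicon("sampleB", pe.RepliconClass.CHROMOSOME, 4000),
            "sampleB_plasmid1": pe.Replicon("sampleB", pe.RepliconClass.PLASMID, 500),
            "sampleB_plasmid2": pe.Replicon("sampleB", pe.RepliconClass.PLASMID, 300),
        }
    )


@pytest.fixture(scope="session")
def sim_small():
    """A small seeded run with rejection active and pore death off."""
    mix = pe.single_sample_mix(plasmid_abundance=0.1)
    flowcell = pe.FlowCellConfig(
        channels_as=8,
        channels_control=8,
        run_hours=2.0,
        channel_lifetime=pe.NO_PORE_DEATH,
    )
    return pe.simulate_run(flowcell, mix, seed=7)
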