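import numpy as np
import pysam
import pytest

from wchrom.covprof import SexCoverageProfile
from wchrom.tracks import DepthTrack


def make_sam(path, lengths, reads, sort_order="coordinate"):
    """Write a small SAM file for tests.

    ``reads`` is a list of dicts with keys: name, ref, pos, cigar and
    optional flag, tags (dict). Records are written in coordinate order by
    default.
    """
    header = {
        "HD": {"VN": "1.6", "SO": sort_order} if sort_order else {"VN": "1.6"},
        "SQ": [{"SN": name, "LN": length} for name, length in lengths.items()],
    }
    tid = {name: i for i, name in enumerate(lengths)}
    if sort_order == "coordinate":
        reads = sorted(reads, key=lambda r: (tid[r["ref"]], r["pos"]))
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for spec in reads:
            a = pysam.AlignedSegment(out.header)
            a.query_name = spec["name"]
            a.reference_id = tid[spec["ref"]]
            a.reference_start = spec["pos"]
            a.cigarstring = spec["cigar"]
            a.flag = spec.get("flag", 0)
            a.mapping_quality = spec.get("mapq", 60)
            qlen = a.infer_query_length()
            a.query_sequence = "A" * qlen if qlen else None
            if "mate_ref" in spec:
                a.next_reference_id = tid[spec["mate_ref"]]
                a.next_reference_start = spec["mate_pos"]
            for tag, value in spec.get("tags", {}).items():
                a.set_tag(tag, value)
            out.write(a)
    return path


def profile_from_arrays(cf, cm, n_f=2, n_m=2, adjustment=1.0, scaffold="s"):
    """SexCoverageProfile straight from per-base pooled depth arrays."""
    f = DepthTrack({scaffold: np.asarray(cf, dtype=np.int64)})
    m = DepthTrack({scaffold: np.asarray(cm, dtype=np.int64)})
    return SexCoverageProfile(
        female_track=f,
        male_track=m,
        modal_f=max(1, int(np.bincount(f[scaffold])[1:].argmax()) + 1) if f[scaffold].max() else 1,
        modal_m=max(1, int(np.bincount(m[scaffold])[1:].argmax()) + 1) if m[scaffold].max() else 1,
        n_females=n_f,
        n_males=n_m,
        adjustment=adjustment,
    )


@pytest.fixture
def sam_factory(tmp_path):
    def _build(reads, lengths=None, name="test.sam", sort_order="coordinate"):
        lengths = lengths or {"s1": 1000}
        return make_sam(tmp_path / name, lengths, reads, sort_order=sort_order)

    return _build
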