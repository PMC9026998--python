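from maml2rwe.cohort import (
    CaseRecord,
    FinalDx,
    FusionCall,
    MarkerStatus,
    PrimarySite,
    WorkingDx,
)


def make_case(surg_signout, mol_order, mol_signout, working="MEC", final="MEC",
              marker="negative"):
    """Minimal valid case with the given timeline and diagnosis labels."""
    fusion = FusionCall("CRTC1", 1, "MAML2", 2) if marker == "positive" else None
    return CaseRecord(
        case_id="X",
        primary_site=PrimarySite.HEAD_AND_NECK,
        working_dx=WorkingDx(working),
        final_dx=FinalDx(final),
        marker_status=MarkerStatus(marker),
        fusion=fusion,
        t_surg_order=0,
        t_surg_signout=surg_signout,
        t_mol_order=mol_order,
        t_mol_signout=mol_signout,
    )
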