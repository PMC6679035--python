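"""Published reference values for the validated TEM sizing workflow.

These constants are the inputs for arithmetic-closure checks and for
configuring real analyses: instrument working-range rows per selected
magnification, the intra-laboratory uncertainty budgets reported by
three experienced partner labs, the trueness assessment against the two
certified colloidal-silica reference materials, and the interlaboratory
(ISO 5725-2) precision summary.  Uncertainty components are relative
percentages unless a column is explicitly in nm.
"""

from __future__ import annotations

CAMERA_PIXELS = 4096  # 4k x 4k CCD

# material, magnification label, FOV edge (nm), printed LOD/LLOQ/ULOQ (nm), mode
IMAGING_CONFIGS = [
    ("ERM-FD100", "18,500x", 2450.0, 0.60, 6.0, 245.0, "default"),
    ("ERM-FD100", "68,000x", 660.0, 0.16, 1.6, 66.0, "default"),
    ("ERM-FD304", "18,500x", 2450.0, 0.60, 6.0, 245.0, "default"),
    ("ERM-FD304", "68,000x", 660.0, 0.16, 1.6, 66.0, "default"),
    ("Gold nanorods", "18,500x", 2450.0, 0.60, 6.0, 245.0, "irregular_watershed"),
    ("NM-100", "9,300x", 4777.0, 1.17, 11.7, 477.7, "ellipse_fitting"),
    ("NM-103", "30,000x", 1537.0, 0.38, 3.8, 153.7, "single_particle"),
    ("NM-212", "30,000x", 1537.0, 0.38, 3.8, 153.7, "single_particle"),
]

# calibration uncertainty (%, k=1) per magnification label
U_CAL_PCT = {"18,500x": 1.0, "9,300x": 0.8, "68,000x": 0.2, "30,000x": 0.1}

# certified / indicative modal ECD references: value (nm), standard
# uncertainty (k=1, nm).  The half-ULP-resolved standard uncertainties
# 0.65/0.75 nm are consistent with the printed budget components; the
# trueness table prints them rounded to 0.7/0.8 nm.
CRM_REFERENCES = {
    "ERM-FD100": {"value_nm": 19.4, "u_nm": 0.65},
    "ERM-FD304": {"value_nm": 27.8, "u_nm": 0.75},
}


def u_t_crm_pct(material: str) -> float:
    """Relative trueness component fed into the uncertainty budget.

    For the two silica CRMs this is their own u_CRM relative to the
    certified value; materials without a reference get the mean of the
    two CRM components.
    """
    comps = {
        m: 100.0 * ref["u_nm"] / ref["value_nm"] for m, ref in CRM_REFERENCES.items()
    }
    return comps.get(material, sum(comps.values()) / len(comps))


# intra-laboratory uncertainty budgets: per material/magnification and
# partner lab; C_m and sd in nm, everything else in %
BUDGET_TABLE = {
    ("ERM-FD100 18,500x", "P1"): dict(cm=17.4, sd=0.3, u_r=1.5, u_day=1.0, u_ip=1.8, u_cal=1.0, u_t=3.8, u_c=4.3, ucx=8.6),
    ("ERM-FD100 18,500x", "P2"): dict(cm=17.5, sd=0.3, u_r=1.5, u_day=1.1, u_ip=1.9, u_cal=1.0, u_t=4.1, u_c=4.7, ucx=9.5),
    ("ERM-FD100 18,500x", "P3"): dict(cm=17.3, sd=0.3, u_r=1.7, u_day=0.6, u_ip=1.7, u_cal=1.0, u_t=3.7, u_c=4.3, ucx=8.6),
    ("ERM-FD100 68,000x", "P1"): dict(cm=18.1, sd=0.3, u_r=1.5, u_day=1.2, u_ip=1.9, u_cal=0.2, u_t=3.9, u_c=4.3, ucx=8.6),
    ("ERM-FD100 68,000x", "P2"): dict(cm=18.4, sd=0.4, u_r=2.0, u_day=1.0, u_ip=2.3, u_cal=0.2, u_t=4.1, u_c=4.6, ucx=9.3),
    ("ERM-FD100 68,000x", "P3"): dict(cm=17.3, sd=0.4, u_r=1.5, u_day=1.8, u_ip=2.4, u_cal=0.2, u_t=4.1, u_c=4.7, ucx=9.5),
    ("ERM-FD304 18,500x", "P1"): dict(cm=22.9, sd=0.3, u_r=1.2, u_day=0.5, u_ip=1.3, u_cal=1.0, u_t=3.0, u_c=3.4, ucx=6.8),
    ("ERM-FD304 18,500x", "P2"): dict(cm=23.3, sd=0.7, u_r=1.2, u_day=2.8, u_ip=3.0, u_cal=1.0, u_t=4.0, u_c=5.1, ucx=10.3),
    ("ERM-FD304 18,500x", "P3"): dict(cm=22.8, sd=0.3, u_r=1.3, u_day=0.5, u_ip=1.4, u_cal=1.0, u_t=3.0, u_c=3.5, ucx=7.0),
    ("ERM-FD304 68,000x", "P1"): dict(cm=23.0, sd=0.3, u_r=1.5, u_day=0.4, u_ip=1.5, u_cal=0.2, u_t=3.1, u_c=3.5, ucx=6.9),
    ("ERM-FD304 68,000x", "P2"): dict(cm=23.5, sd=0.5, u_r=1.2, u_day=1.9, u_ip=2.2, u_cal=0.2, u_t=3.5, u_c=4.1, ucx=8.3),
    ("ERM-FD304 68,000x", "P3"): dict(cm=23.0, sd=0.4, u_r=1.7, u_day=0.7, u_ip=1.8, u_cal=0.2, u_t=3.3, u_c=3.8, ucx=7.5),
    ("Gold nanorods", "P1"): dict(cm=15.8, sd=0.5, u_r=3.1, u_day=1.2, u_ip=3.4, u_cal=1.0, u_t=4.5, u_c=5.7, ucx=11.4),
    ("Gold nanorods", "P2"): dict(cm=15.1, sd=1.0, u_r=6.9, u_day=2.7, u_ip=7.4, u_cal=1.0, u_t=8.0, u_c=10.9, ucx=21.9),
    ("Gold nanorods", "P3"): dict(cm=15.2, sd=0.7, u_r=4.0, u_day=1.7, u_ip=4.4, u_cal=1.0, u_t=5.3, u_c=6.9, ucx=13.9),
    ("NM-100", "P1"): dict(cm=100.0, sd=2.0, u_r=1.9, u_day=0.7, u_ip=2.1, u_cal=0.8, u_t=3.6, u_c=4.3, ucx=8.5),
    ("NM-100", "P2"): dict(cm=103.0, sd=3.0, u_r=2.6, u_day=0.5, u_ip=2.6, u_cal=0.8, u_t=4.0, u_c=4.8, ucx=9.7),
    ("NM-100", "P3"): dict(cm=105.0, sd=2.0, u_r=2.2, u_day=0.7, u_ip=2.3, u_cal=0.8, u_t=3.8, u_c=4.5, ucx=9.0),
    ("NM-103", "P1"): dict(cm=18.2, sd=0.4, u_r=2.1, u_day=1.3, u_ip=2.5, u_cal=0.1, u_t=3.9, u_c=4.6, ucx=9.2),
    ("NM-103", "P2"): dict(cm=21.4, sd=0.7, u_r=2.6, u_day=1.8, u_ip=3.1, u_cal=0.1, u_t=4.3, u_c=5.3, ucx=10.7),
    ("NM-103", "P3"): dict(cm=21.3, sd=0.4, u_r=2.0, u_day=0.8, u_ip=2.1, u_cal=0.1, u_t=3.7, u_c=4.3, ucx=8.5),
    ("NM-212", "P1"): dict(cm=15.6, sd=1.0, u_r=6.4, u_day=2.0, u_ip=6.7, u_cal=0.1, u_t=7.3, u_c=9.9, ucx=19.9),
    ("NM-212", "P2"): dict(cm=15.6, sd=1.4, u_r=8.5, u_day=3.0, u_ip=9.0, u_cal=0.1, u_t=9.5, u_c=13.1, ucx=26.2),
    ("NM-212", "P3"): dict(cm=17.6, sd=1.1, u_r=6.3, u_day=0.8, u_ip=6.3, u_cal=0.1, u_t=7.0, u_c=9.4, ucx=18.9),
}

# trueness assessment on modal ECD; all columns in nm
TRUENESS_TABLE = [
    dict(material="ERM-FD100", mag="18,500x", cm=19.2, uc=0.9, c_crm=19.4, u_crm=0.7, dm=0.2, u_delta=1.1, U_delta=2.3),
    dict(material="ERM-FD100", mag="68,000x", cm=19.4, uc=0.8, c_crm=19.4, u_crm=0.7, dm=0.0, u_delta=1.1, U_delta=2.1),
    dict(material="ERM-FD304", mag="18,500x", cm=25.5, uc=1.3, c_crm=27.8, u_crm=0.8, dm=2.3, u_delta=1.5, U_delta=3.1),
    dict(material="ERM-FD304", mag="68,000x", cm=24.9, uc=1.0, c_crm=27.8, u_crm=0.8, dm=2.9, u_delta=1.3, U_delta=2.6),
]

# interlaboratory precision summary (after outlier rejection)
INTERLAB_TABLE = {
    "ERM-FD100": dict(n_labs=17, x_obs=17.4, s_r=0.3, r=0.8, rsd_r=1.8, s_R=0.3, R=0.9, rsd_R=1.8),
    "Gold nanorods": dict(n_labs=19, x_obs=15.93, s_r=0.7, r=2.0, rsd_r=4.6, s_R=0.8, R=2.2, rsd_R=5.2),
    "NM-100": dict(n_labs=18, x_obs=97.4, s_r=4.7, r=13.2, rsd_r=4.8, s_R=5.7, R=15.9, rsd_R=5.8),
    "NM-212": dict(n_labs=18, x_obs=13.7, s_r=1.0, r=2.9, rsd_r=7.5, s_R=1.8, R=5.2, rsd_R=13.6),
}
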