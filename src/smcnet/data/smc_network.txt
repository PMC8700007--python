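# Vascular smooth muscle cell mTOR signaling network (81 species, 138 reactions).
#
# This file is a reconstruction of an aortic SMC signaling map: mechanical
# (intramural/wall shear stress), metabolic (oxygen, cellular energy, glucose,
# leucine), matrix (fibrillin) and exogenous (angiotensin II, IFN-gamma)
# inputs converge through seven cell-surface receptor reactions onto the
# PI3K/AKT/mTOR axis, with MAPK, Smad, Rho/ROCK, Wnt/beta-catenin and
# NF-kB crosstalk, and readouts for contractile proteins, matrix turnover
# and lysosomal/degradative species.  Weights follow uniform class values
# (inputs as annotated; receptor reactions w=0.85; downstream reactions
# w=1) and a single model-wide Hill parameterization (n=1.4, EC50=0.52).
#
# Grammar: `species NAME [role=..] [ymax=..] [tau=..] [y0=..]` declarations,
# then rules `LHS => TARGET [w=..]`, where LHS is `&`-separated terms,
# `!` marks inhibition, and an empty LHS declares an input reaction.
# Rules sharing a target combine by inclusive OR.
hill n=1.4 ec50=0.52

# ---- inputs ----
species Stress role=input
species ShearStress role=input
species AngII_ex role=input
species IFNg_ex role=input
species Oxygen role=input
species Energy role=input
species Glucose role=input
species Leucine role=input
species Fibrillin role=input

# ---- extracellular ligands ----
species IGF1
species TGFB
species PDGF
species AngII
species Wnt
species IFNg
species IL1
species IL6

# ---- receptors ----
species IGFR role=receptor
species TGFBR role=receptor
species PDGFR role=receptor
species AT1R role=receptor
species FZD role=receptor
species IntegrinB1 role=receptor
species IFNGR role=receptor

# ---- intracellular ----
species IRS1
species PI3K
species PDK1
species AKT
species mTOR
species mTORC2
species mTORC1
species TSC1_2
species Rheb
species S6K
species S6
species E4EBP1
species eIF4E
species GSK3
species bCatenin
species MITF
species LAMP1
species LAMP2
species FOXO
species RhoA
species ROCK
species MLC
species SRF
species MyoCD
species KLF4
species Smad2_3
species Smad4
species Smad7
species Ras
species Raf
species MEK
species ERK
species MKK3_6
species p38
species MKK4
species JNK
species TAK1
species IKK
species NFkB
species ROS
species AMPK
species ULK1
species STAT1
species PLC
species PKC
species Ca

# ---- outputs / phenotype species ----
species SMMHC role=output
species SMA role=output
species SM22 role=output
species Col3a1 role=output
species Eln role=output
species TIMP role=output
species MMP2 role=output
species MMP9 role=output
species Collagen role=output
species Elastin role=output
species ElastinDegraded role=output

# ---- input reactions ----
=> Stress w=0.24054
=> ShearStress w=0.24054
=> AngII_ex w=0.0
=> IFNg_ex w=0.0
=> Oxygen w=0.5
=> Energy w=0.5
=> Glucose w=0.25
=> Leucine w=0.25
=> Fibrillin w=0.25

# ---- ligand production ----
Glucose & Energy => IGF1
Stress => TGFB
!Fibrillin => TGFB
ShearStress => PDGF
Stress => PDGF
AngII_ex => AngII
Stress => AngII
AngII => TGFB
Stress => Wnt
IFNg_ex => IFNg
NFkB => IL1
IFNg => IL1
NFkB => IL6
STAT1 => IL6

# ---- receptor reactions (the 7 sampled in population runs) ----
IGF1 => IGFR w=0.85
TGFB => TGFBR w=0.85
PDGF => PDGFR w=0.85
AngII => AT1R w=0.85
Wnt => FZD w=0.85
Stress => IntegrinB1 w=0.85
IFNg => IFNGR w=0.85

# ---- PI3K/AKT/mTOR axis ----
IGFR & !S6K => IRS1
IGFR & !S6K => PI3K
IRS1 & !S6K => PI3K
IntegrinB1 & Energy => PI3K
PKC => PI3K
PDGFR => PI3K
PI3K => PDK1
PDK1 => AKT
mTORC2 => AKT
AKT => mTOR
mTOR => mTORC2
GSK3 & !AKT => TSC1_2
TGFBR => TSC1_2
AMPK => TSC1_2
!TSC1_2 => Rheb
Rheb => mTORC1
Rheb & Leucine => mTORC1
mTORC1 => S6K
S6K => S6
mTORC1 => E4EBP1
E4EBP1 => eIF4E
S6K => eIF4E
ERK => eIF4E

# ---- GSK3 / Wnt / lysosome ----
!S6K & !FZD => GSK3
!GSK3 => bCatenin
FZD => bCatenin
S6 & !GSK3 => MITF
MITF => LAMP1
MITF => LAMP2
AMPK & !mTORC1 => ULK1
MITF => ULK1
ULK1 & MITF => LAMP1
ULK1 & MITF => LAMP2

# ---- apoptosis / energy / stress ----
!AKT => FOXO
AMPK => FOXO
!Energy => AMPK
mTORC1 => ROS
Oxygen => ROS
AT1R => ROS
Stress => ROS
ROS => MKK3_6
TAK1 => MKK3_6
MKK3_6 => p38
STAT1 => p38
ROS => p38
TAK1 => MKK4
ROS => MKK4
MKK4 => JNK
PDGFR => JNK
ROS => JNK
TAK1 & ROS => IKK
IFNGR => IKK
PKC => NFkB
IKK => NFkB
IFNGR => NFkB
TGFBR => TAK1
IL1 => TAK1
IFNGR => STAT1
IL6 => STAT1

# ---- MAPK / ERK ----
PDGFR => Ras
IntegrinB1 => Ras
IGFR => Ras
AT1R => Ras
Ras => Raf
PKC => Raf
Raf => MEK
MEK => ERK
ERK => KLF4
IFNGR => KLF4

# ---- contractile machinery ----
AT1R => PLC
PLC => PKC
PLC => Ca
Ca => MLC
ROCK => MLC
RhoA => MLC
mTORC2 => RhoA
IntegrinB1 => RhoA
AT1R => RhoA
RhoA => ROCK
ROCK => SRF
AKT => SRF
SRF & !KLF4 => MyoCD
Smad2_3 => MyoCD
MyoCD => SMMHC
SRF & !KLF4 => SMMHC
MyoCD => SMA
MyoCD => SM22

# ---- TGFbeta / Smad / ECM ----
TGFBR & !Smad7 => Smad2_3
TSC1_2 & TGFBR & !Smad7 => Smad2_3
TGFBR => Smad7
Smad2_3 => Smad7
Smad2_3 => Smad4
Smad4 => Col3a1
Smad2_3 => Col3a1
Smad4 & !S6K => Eln
Smad4 => TIMP
TGFBR => TIMP
bCatenin & !TIMP => MMP2
ERK => MMP2
NFkB => MMP2
NFkB => MMP9
p38 => MMP9
JNK => MMP9
Col3a1 => Collagen
Smad4 => Collagen
Eln & !MMP2 => Elastin
MMP2 & Elastin => ElastinDegraded
MMP9 & Elastin => ElastinDegraded
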