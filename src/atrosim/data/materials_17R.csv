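label,mu_kPa,alpha,nu,provenance
FC,1.82,-21.0,0.49,placeholder cortical stiffness; edit to fitted values
MC,1.66,-19.5,0.49,placeholder cortical stiffness; edit to fitted values
VC,1.18,-23.0,0.49,placeholder cortical stiffness; edit to fitted values
CI,1.44,-18.0,0.49,placeholder cortical stiffness; edit to fitted values
TL,1.58,-20.0,0.49,placeholder cortical stiffness; edit to fitted values
CR,1.25,-16.5,0.49,placeholder white-matter stiffness; edit to fitted values
NC,0.66,-14.0,0.49,placeholder deep-gray stiffness; edit to fitted values
Pa,0.83,-13.5,0.49,placeholder deep-gray stiffness; edit to fitted values
Pu,0.77,-14.5,0.49,placeholder deep-gray stiffness; edit to fitted values
Me,0.75,-12.0,0.49,placeholder brainstem stiffness; edit to fitted values
P,0.68,-12.5,0.49,placeholder brainstem stiffness; edit to fitted values
M,0.82,-13.0,0.49,placeholder brainstem stiffness; edit to fitted values
Th,0.90,-15.0,0.49,placeholder deep-gray stiffness; edit to fitted values
CB,1.06,-17.0,0.49,placeholder cerebellar stiffness; edit to fitted values
Am,0.86,-14.0,0.49,placeholder limbic stiffness; edit to fitted values
Hi,0.79,-15.5,0.49,placeholder limbic stiffness; edit to fitted values
CC,0.73,-24.0,0.49,placeholder callosal stiffness; edit to fitted values
CSF,0.1536,2.0,0.3,ultrasoft compressible solid; mu = mean cortical mu / 10
VENTRICLE,0.1536,2.0,0.3,ventricular cavity modeled as CSF-like ultrasoft solid
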