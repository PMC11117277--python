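code,name,class
piperacillin_tazobactam,Piperacillin/tazobactam,anti_pseudomonal
meropenem,Meropenem,anti_pseudomonal
imipenem_cilastatin,Imipenem/cilastatin,anti_pseudomonal
doripenem,Doripenem,anti_pseudomonal
levofloxacin,Levofloxacin,anti_pseudomonal
ciprofloxacin,Ciprofloxacin,anti_pseudomonal
cefepime,Cefepime,anti_pseudomonal
ceftazidime,Ceftazidime,anti_pseudomonal
aztreonam,Aztreonam,anti_pseudomonal
ampicillin_sulbactam,Ampicillin/sulbactam,non_anti_pseudomonal
ceftriaxone,Ceftriaxone,non_anti_pseudomonal
cefotaxime,Cefotaxime,non_anti_pseudomonal
cefazolin,Cefazolin,non_anti_pseudomonal
clindamycin,Clindamycin,non_anti_pseudomonal
vancomycin,Vancomycin,non_anti_pseudomonal
metronidazole,Metronidazole,non_anti_pseudomonal
noradrenaline,Noradrenaline,vasopressor
adrenaline,Adrenaline,vasopressor
dopamine,Dopamine,vasopressor
dobutamine,Dobutamine,vasopressor
vasopressin,Vasopressin,vasopressor
urokinase,Urokinase,other
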