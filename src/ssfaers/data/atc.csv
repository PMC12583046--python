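generic,atc_code
fluoxetine,N
sertraline,N
paroxetine,N
citalopram,N
escitalopram,N
venlafaxine,N
duloxetine,N
mirtazapine,N
trazodone,N
bupropion,N
amitriptyline,N
nortriptyline,N
clomipramine,N
phenelzine,N
selegiline,N
tramadol,N
fentanyl,N
oxycodone,N
methadone,N
buspirone,N
lithium,N
quetiapine,N
risperidone,N
olanzapine,N
aripiprazole,N
lamotrigine,N
lacosamide,N
gabapentin,N
pregabalin,N
sumatriptan,N
linezolid,J
ciprofloxacin,J
fluconazole,J
azithromycin,J
isoniazid,J
metronidazole,J
metoclopramide,A
ondansetron,A
granisetron,A
omeprazole,A
loperamide,A
sitagliptin,A
cyclobenzaprine,M
methocarbamol,M
celecoxib,M
isotretinoin,D
calcipotriol,D
methylthioninium chloride,V
iohexol,V
dextromethorphan,R
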