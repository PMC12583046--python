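raw,generic,source
FLUOXETINE,fluoxetine,generic identity
PROZAC,fluoxetine,trade name
SERTRALINE,sertraline,generic identity
ZOLOFT,sertraline,trade name
PAROXETINE,paroxetine,generic identity
PAXIL,paroxetine,trade name
CITALOPRAM,citalopram,generic identity
CELEXA,citalopram,trade name
ESCITALOPRAM,escitalopram,generic identity
LEXAPRO,escitalopram,trade name
VENLAFAXINE,venlafaxine,generic identity
EFFEXOR,venlafaxine,trade name
DULOXETINE,duloxetine,generic identity
CYMBALTA,duloxetine,trade name
MIRTAZAPINE,mirtazapine,generic identity
REMERON,mirtazapine,trade name
TRAZODONE,trazodone,generic identity
DESYREL,trazodone,trade name
BUPROPION,bupropion,generic identity
WELLBUTRIN,bupropion,trade name
AMITRIPTYLINE,amitriptyline,generic identity
ELAVIL,amitriptyline,trade name
NORTRIPTYLINE,nortriptyline,generic identity
PAMELOR,nortriptyline,trade name
CLOMIPRAMINE,clomipramine,generic identity
ANAFRANIL,clomipramine,trade name
PHENELZINE,phenelzine,generic identity
NARDIL,phenelzine,trade name
SELEGILINE,selegiline,generic identity
EMSAM,selegiline,trade name
TRAMADOL,tramadol,generic identity
ULTRAM,tramadol,trade name
FENTANYL,fentanyl,generic identity
DURAGESIC,fentanyl,trade name
OXYCODONE,oxycodone,generic identity
OXYCONTIN,oxycodone,trade name
METHADONE,methadone,generic identity
DOLOPHINE,methadone,trade name
BUSPIRONE,buspirone,generic identity
BUSPAR,buspirone,trade name
LITHIUM,lithium,generic identity
ESKALITH,lithium,trade name
QUETIAPINE,quetiapine,generic identity
SEROQUEL,quetiapine,trade name
RISPERIDONE,risperidone,generic identity
RISPERDAL,risperidone,trade name
OLANZAPINE,olanzapine,generic identity
ZYPREXA,olanzapine,trade name
ARIPIPRAZOLE,aripiprazole,generic identity
ABILIFY,aripiprazole,trade name
LAMOTRIGINE,lamotrigine,generic identity
LAMICTAL,lamotrigine,trade name
LACOSAMIDE,lacosamide,generic identity
VIMPAT,lacosamide,trade name
GABAPENTIN,gabapentin,generic identity
NEURONTIN,gabapentin,trade name
PREGABALIN,pregabalin,generic identity
LYRICA,pregabalin,trade name
SUMATRIPTAN,sumatriptan,generic identity
IMITREX,sumatriptan,trade name
LINEZOLID,linezolid,generic identity
ZYVOX,linezolid,trade name
CIPROFLOXACIN,ciprofloxacin,generic identity
CIPRO,ciprofloxacin,trade name
FLUCONAZOLE,fluconazole,generic identity
DIFLUCAN,fluconazole,trade name
AZITHROMYCIN,azithromycin,generic identity
ZITHROMAX,azithromycin,trade name
ISONIAZID,isoniazid,generic identity
METRONIDAZOLE,metronidazole,generic identity
FLAGYL,metronidazole,trade name
METOCLOPRAMIDE,metoclopramide,generic identity
REGLAN,metoclopramide,trade name
ONDANSETRON,ondansetron,generic identity
ZOFRAN,ondansetron,trade name
GRANISETRON,granisetron,generic identity
KYTRIL,granisetron,trade name
OMEPRAZOLE,omeprazole,generic identity
PRILOSEC,omeprazole,trade name
LOPERAMIDE,loperamide,generic identity
IMODIUM,loperamide,trade name
SITAGLIPTIN,sitagliptin,generic identity
JANUVIA,sitagliptin,trade name
CYCLOBENZAPRINE,cyclobenzaprine,generic identity
FLEXERIL,cyclobenzaprine,trade name
METHOCARBAMOL,methocarbamol,generic identity
ROBAXIN,methocarbamol,trade name
CELECOXIB,celecoxib,generic identity
CELEBREX,celecoxib,trade name
ISOTRETINOIN,isotretinoin,generic identity
ACCUTANE,isotretinoin,trade name
CALCIPOTRIOL,calcipotriol,generic identity
DOVONEX,calcipotriol,trade name
METHYLTHIONINIUM CHLORIDE,methylthioninium chloride,generic identity
METHYLENE BLUE,methylthioninium chloride,trade name
IOHEXOL,iohexol,generic identity
OMNIPAQUE,iohexol,trade name
DEXTROMETHORPHAN,dextromethorphan,generic identity
DELSYM,dextromethorphan,trade name
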