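group,nutrient,value,unit,rule,citation
children,energy,1600,kcal/day,EER,IOM 2005 DRI Energy
women,energy,2000,kcal/day,EER,IOM 2005 DRI Energy
men,energy,2600,kcal/day,EER,IOM 2005 DRI Energy
children,protein,15,g/day,EAR,IOM 2005 DRI Macronutrients
women,protein,38,g/day,EAR,IOM 2005 DRI Macronutrients
men,protein,46,g/day,EAR,IOM 2005 DRI Macronutrients
children,total_fat,53.3,g/day,AMDR-midpoint,IOM 2005 (30% of energy / 9 kcal per g)
women,total_fat,66.7,g/day,AMDR-midpoint,IOM 2005 (30% of energy / 9 kcal per g)
men,total_fat,86.7,g/day,AMDR-midpoint,IOM 2005 (30% of energy / 9 kcal per g)
children,iron,4.1,mg/day,EAR,IOM 2001 DRI Micronutrients
women,iron,8.1,mg/day,EAR,IOM 2001 DRI Micronutrients
men,iron,6.0,mg/day,EAR,IOM 2001 DRI Micronutrients
children,zinc,4.0,mg/day,EAR,IOM 2001 DRI Micronutrients
women,zinc,6.8,mg/day,EAR,IOM 2001 DRI Micronutrients
men,zinc,9.4,mg/day,EAR,IOM 2001 DRI Micronutrients
children,selenium,23,ug/day,EAR,IOM 2000 DRI Antioxidants
women,selenium,45,ug/day,EAR,IOM 2000 DRI Antioxidants
men,selenium,45,ug/day,EAR,IOM 2000 DRI Antioxidants
children,vitamin_b1,0.5,mg/day,EAR,IOM 1998 DRI B vitamins
women,vitamin_b1,0.9,mg/day,EAR,IOM 1998 DRI B vitamins
men,vitamin_b1,1.0,mg/day,EAR,IOM 1998 DRI B vitamins
children,vitamin_b2,0.5,mg/day,EAR,IOM 1998 DRI B vitamins
women,vitamin_b2,0.9,mg/day,EAR,IOM 1998 DRI B vitamins
men,vitamin_b2,1.1,mg/day,EAR,IOM 1998 DRI B vitamins
children,vitamin_b3,6,mg/day,EAR,IOM 1998 DRI B vitamins
women,vitamin_b3,11,mg/day,EAR,IOM 1998 DRI B vitamins
men,vitamin_b3,12,mg/day,EAR,IOM 1998 DRI B vitamins
children,vitamin_b12,1.0,ug/day,EAR,IOM 1998 DRI B vitamins
women,vitamin_b12,2.0,ug/day,EAR,IOM 1998 DRI B vitamins
men,vitamin_b12,2.0,ug/day,EAR,IOM 1998 DRI B vitamins
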