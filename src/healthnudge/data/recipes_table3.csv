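id,name,query_type,fat,sat_fat,sugar,salt,mean_rating,image_ref,image_z,fsa_printed
burger-01,Backyard black bean burgers,burger,1.29,0.22,2.05,1.27,4,,1.44,5
burger-02,Burgers chili dog style,burger,9.75,4.60,1.79,1.12,4.67,,0.09,9
burger-03,Butter bean burgers,burger,11.90,3.31,1.07,0.78,4.38,,-0.33,7
burger-04,Cajun burgers,burger,17.20,6.05,0.70,1.07,3.5,,0.99,9
burger-05,Carrot burgers,burger,14.37,2.37,4.62,0.94,4.4,,0.43,7
burger-06,Cheddar bacon burgers,burger,12.16,5.24,1.78,1.44,4.55,,0.00,9
burger-07,Pizza burgers,burger,6.36,2.64,3.72,0.96,3,,1.18,9
burger-08,Pumpkin bean burgers,burger,7.72,1.26,2.73,0.45,4,,1.54,6
curry-01,Curried chicken and potatoes,curry,4.76,1.07,2.07,0.37,4.13,,0.57,6
curry-02,Curry chicken and brown rice casserole,curry,0.81,0.20,5.88,0.63,4.29,,0.18,6
curry-03,Curry chicken with rice,curry,13.28,3.26,7.11,0.12,4,,-0.70,10
curry-04,Curry mango chicken,curry,6.87,2.80,4.10,0.33,4,,-0.37,9
curry-05,Curry sausage couscous,curry,15.46,5.03,0.67,0.71,5,,0.52,9
curry-06,Curry-coconut shrimp,curry,3.12,1.08,1.43,0.23,4.05,,-0.02,5
curry-07,Turkey curry,curry,5.87,1.37,1.09,0.10,3.5,,-0.67,5
curry-08,Turkey curry with cashews,curry,10.25,2.59,1.19,0.44,4,,0.70,9
pasta-01,Fusili pasta with broccoli,pasta,0.78,0.12,5.64,0.03,4.5,,1.56,5
pasta-02,Pasta pomodoro,pasta,5.67,0.90,2.01,0.27,4.53,,1.11,5
pasta-03,Pasta sauce with Italian sausage,pasta,8.76,3.03,2.10,1.35,4.7,,1.43,9
pasta-04,Pasta with chicken and roasted pepper cream sauce,pasta,10.54,5.86,1.37,1.14,4,,0.27,9
pasta-05,Pasta with fresh vegetables,pasta,9.12,1.62,3.05,1.75,4.63,,0.98,9
pasta-06,Pasta with lentil soup sauce,pasta,0.90,0.16,0.79,0.33,5,,-0.53,5
pasta-07,Pasta with Salami and Peas,pasta,17.68,5.78,1.98,1.12,4,,-0.46,9
pasta-08,Pasta with spinach and smoked sausage,pasta,2.54,0.57,1.64,0.50,4.75,,0.13,5
salad-01,Caesar salad with cilantro and green chile dressing,salad,27.26,5.06,1.49,1.01,4.5,,0.13,9
salad-02,Cucumber-carrot salad,salad,0.77,0.11,3.67,0.47,4.29,,0.55,5
salad-03,"Curried cashew, pear, and grape salad",salad,19.67,3.97,8.14,0.99,4.92,,0.71,10
salad-04,Shaved asparagus salad,salad,7.59,1.40,1.28,0.55,5,,0.13,6
salad-05,Tomato bacon salad,salad,11.81,3.27,1.44,1.24,0,,1.54,10
salad-06,"Tomato, basil, and corn salad with apple cider dressing",salad,6.37,0.87,1.57,0.22,5,,1.51,5
salad-07,Tomato-basil salad,salad,5.23,1.35,2.64,0.18,5,,0.99,5
salad-08,"Tricolore salad of endive, beet, and arugula, pantzaria salata",salad,39.31,6.32,2.53,1.02,4.67,,0.96,9
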