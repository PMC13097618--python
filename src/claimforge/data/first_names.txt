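Jonathan
Maria
James
Linda
Robert
Patricia
Michael
Barbara
William
Elizabeth
David
Jennifer
Richard
Susan
Joseph
Jessica
Thomas
Sarah
Charles
Karen
Christopher
Nancy
Daniel
Lisa
Matthew
Betty
Anthony
Margaret
Mark
Sandra
Donald
Ashley
Steven
Kimberly
Paul
Emily
Andrew
Donna
Joshua
Michelle
Kenneth
Dorothy
Kevin
Carol
Brian
Amanda
George
Melissa
Edward
Deborah
Ronald
Stephanie
Timothy
Rebecca
Jason
Sharon
Jeffrey
Laura
Ryan
Cynthia
Jacob
Kathleen
Gary
Amy
Nicholas
Angela
Eric
Shirley
Anna
Stephen
Brenda
Larry
Pamela
Justin
Emma
Scott
Nicole
Brandon
Helen
Benjamin
Samantha
Samuel
Katherine
Gregory
Christine
Frank
Debra
Alexander
Rachel
Raymond
Carolyn
Patrick
Janet
Jack
Catherine
Dennis
Jerry
Heather
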